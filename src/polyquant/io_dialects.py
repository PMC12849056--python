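"""Reading and writing single-profile delimited text exports.

Gradient fractionation instruments export one run per text file, but the
layout differs by vendor software and by the operating system's language
settings: the column delimiter may be a tab, comma, semicolon or a
whitespace run; the decimal separator may be "." or ","; a number of header
lines precede the data; and the UV and (optional) fluorescence traces sit
at particular column ordinals. A :class:`DialectSpec` captures one such
layout.

Built-in presets approximate the exports of common fractionator software
(PeakTrak / Teledyne Isco, TRIAX / BioComp, PrimeView / Äkta). They are
shipped as editable config data, not hard-coded logic, and **must be
verified against your own exports** — vendors change layouts between
versions, and the decimal separator in particular follows the language
settings of the machine that exported the file. Override any field with
:func:`dataclasses.replace` or the ``dialect(...)`` helper.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import MIN_TRACE_LEN, Profile
from .errors import InputError, ParseError, ValidationError

__all__ = [
    "DialectSpec",
    "DIALECT_PRESETS",
    "builtin_dialects",
    "dialect",
    "read_profile",
    "write_fixture",
]

_DELIMITERS = {"\t", ",", ";", "whitespace"}


@dataclass(frozen=True)
class DialectSpec:
    """Layout of a single-profile delimited text export.

    Parameters
    ----------
    name : str
        Label used in sessions and logs.
    delimiter : str
        One of ``"\\t"``, ``","``, ``";"`` or ``"whitespace"`` (any run of
        spaces/tabs).
    decimal_mark : str
        ``"."`` or ``","``. If ``","``, the delimiter must not be ``","``.
    skip_lines : int
        Header lines ignored at the top of the file.
    uv_column : int
        1-based ordinal of the UV absorbance column.
    fluor_column : int or None
        1-based ordinal of the fluorescence column, if any.
    """

    name: str
    delimiter: str
    decimal_mark: str = "."
    skip_lines: int = 0
    uv_column: int = 1
    fluor_column: int | None = None

    def __post_init__(self):
        if self.delimiter not in _DELIMITERS:
            raise ValidationError(
                f"delimiter must be tab, ',', ';' or 'whitespace', got {self.delimiter!r}"
            )
        if self.decimal_mark not in (".", ","):
            raise ValidationError(f"decimal_mark must be '.' or ',', got {self.decimal_mark!r}")
        if self.decimal_mark == "," and self.delimiter == ",":
            raise ValidationError("decimal_mark ',' is incompatible with delimiter ','")
        if self.skip_lines < 0:
            raise ValidationError("skip_lines must be non-negative")
        if self.uv_column < 1:
            raise ValidationError("uv_column must be >= 1")
        if self.fluor_column is not None:
            if self.fluor_column < 1:
                raise ValidationError("fluor_column must be >= 1")
            if self.fluor_column == self.uv_column:
                raise ValidationError("fluor_column must differ from uv_column")

    def replace(self, **overrides) -> "DialectSpec":
        """Return a copy with fields overridden (presets are templates)."""
        return dataclasses.replace(self, **overrides)

    def split(self, line: str) -> list[str]:
        if self.delimiter == "whitespace":
            return line.split()
        return line.split(self.delimiter)


#: Editable preset table. Values are provisional defaults for the named
#: vendor software; verify them against your own exports before use.
DIALECT_PRESETS: dict[str, dict] = {
    "peaktrak": dict(delimiter="\t", decimal_mark=".", skip_lines=4, uv_column=1),
    "triax": dict(delimiter=",", decimal_mark=".", skip_lines=1, uv_column=2),
    "primeview": dict(delimiter="\t", decimal_mark=".", skip_lines=2, uv_column=2),
    # Generic starting point: override every field to match your export.
    "custom": dict(delimiter="\t", decimal_mark=".", skip_lines=0, uv_column=1),
}


def dialect(name: str, **overrides) -> DialectSpec:
    """Instantiate a preset by name, with field-by-field overrides."""
    try:
        base = DIALECT_PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown dialect preset {name!r}; known: {sorted(DIALECT_PRESETS)}"
        ) from None
    params = {**base, **overrides}
    return DialectSpec(name=name, **params)


def builtin_dialects() -> list[DialectSpec]:
    """All named presets, instantiated with their default parameters."""
    return [dialect(name) for name in DIALECT_PRESETS]


def _parse_field(token: str, decimal_mark: str, line_no: int) -> float:
    if decimal_mark == ",":
        token = token.replace(",", ".")
    try:
        value = float(token)
    except ValueError:
        raise ParseError(
            f"line {line_no}: cannot parse numeric field {token!r}", line=line_no
        ) from None
    if not np.isfinite(value):
        raise ParseError(f"line {line_no}: non-finite value {token!r}", line=line_no)
    return value


def read_profile(path: str | Path, dialect: DialectSpec, id: str | None = None) -> Profile:
    """Parse one profile file under the given dialect.

    Skips ``skip_lines`` header lines and blank lines, splits each remaining
    line on the delimiter, and reads the UV (and, if configured, the
    fluorescence) value from its 1-based column ordinal. When the decimal
    mark is ",", commas are substituted with "." per field before numeric
    parsing, so parsing does not depend on the environment locale.

    Raises
    ------
    InputError
        The file does not exist.
    ParseError
        A data line has too few columns or a field is not numeric; the
        message names the 1-based line number in the file.
    ValidationError
        The resulting trace is shorter than 3 samples.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"input file not found: {path}")
    uv: list[float] = []
    fluor: list[float] = []
    need = max(dialect.uv_column, dialect.fluor_column or 0)
    with open(path, "r", encoding="utf-8", newline=None) as fh:
        for line_no, raw in enumerate(fh, start=1):
            if line_no <= dialect.skip_lines:
                continue
            line = raw.strip()
            if not line:
                continue
            fields = dialect.split(line)
            if len(fields) < need:
                raise ParseError(
                    f"line {line_no}: expected at least {need} columns, found {len(fields)}",
                    line=line_no,
                )
            uv.append(_parse_field(fields[dialect.uv_column - 1], dialect.decimal_mark, line_no))
            if dialect.fluor_column is not None:
                fluor.append(
                    _parse_field(fields[dialect.fluor_column - 1], dialect.decimal_mark, line_no)
                )
    if len(uv) < MIN_TRACE_LEN:
        raise ValidationError(
            f"{path}: parsed only {len(uv)} data rows; at least {MIN_TRACE_LEN} required"
        )
    return Profile(
        id=id or path.stem,
        uv=np.asarray(uv),
        fluor=np.asarray(fluor) if dialect.fluor_column is not None else None,
        source=str(path),
        dialect_name=dialect.name,
    )


def _format_number(value: float, decimal_mark: str) -> str:
    text = repr(float(value))
    if decimal_mark == ",":
        text = text.replace(".", ",")
    return text


def write_fixture(profile: Profile, dialect: DialectSpec, path: str | Path) -> Path:
    """Write ``profile`` as a text file in the given dialect.

    Emits ``skip_lines`` placeholder header lines, then one data line per
    sample with filler columns ("0") so the UV and fluorescence values land
    at their declared ordinals. Numbers are written with ``repr`` (shortest
    round-trip representation), so ``read_profile(write_fixture(p))``
    reproduces the values exactly.
    """
    path = Path(path)
    sep = " " if dialect.delimiter == "whitespace" else dialect.delimiter
    ncols = max(dialect.uv_column, dialect.fluor_column or 0)
    lines = [f"# header line {i + 1}" for i in range(dialect.skip_lines)]
    for i in range(len(profile)):
        fields = ["0"] * ncols
        fields[dialect.uv_column - 1] = _format_number(profile.uv[i], dialect.decimal_mark)
        if dialect.fluor_column is not None:
            if profile.fluor is None:
                raise ValidationError(
                    "dialect declares a fluorescence column but the profile has no "
                    "fluorescence trace"
                )
            fields[dialect.fluor_column - 1] = _format_number(
                profile.fluor[i], dialect.decimal_mark
            )
        lines.append(sep.join(fields))
    try:
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    except OSError as exc:
        raise InputError(f"cannot write fixture to {path}: {exc}") from exc
    return path
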