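# polyquant

Headless quantification, alignment and Gaussian deconvolution of **polysome
profiles** — the UV absorbance (~260 nm) traces recorded while a
sucrose-density gradient elutes after ultracentrifugation. A profile shows,
in elution order, a detergent peak, the 40S and 60S ribosomal subunit
peaks, the 80S monosome peak, and a decaying train of polysome peaks; the
polysomal area relative to the total area is the standard proxy for global
translational activity. An optional fluorescence trace recorded row-for-row
alongside the UV channel (fluorescent polysome profiling) is analyzed in
parallel.

polyquant is a scriptable library plus CLI for labs that want this analysis
reproducible and automatable rather than clicked together in a spreadsheet:
it parses the delimited text exports of common fractionator software,
subtracts baselines, detects local minima/maxima/inflection points, aligns
replicate profiles along a chosen x-anchor, sums areas over user-defined
regions, deconvolves overlapping peaks into Gaussian components, summarizes
replicates per condition, and records every parameter in a replayable
session file.

## The core quantities

With `y[i]` the signal at sample index `i` and `b` a per-channel scalar
baseline, the area of a region `[s, e]` (both endpoints included) is the
plain sum

    A = Σ_{i=s}^{e} (y[i] − b)

with no x-spacing factor, so relative areas such as Polysomes/Total are
dimensionless. For peak deconvolution, a restricted region is modeled as a
sum of Gaussians

    g_k(x) = h_k · exp(−(x − μ_k)² / (2σ_k²))

Candidate positions are seeded at the negative local minima of the smoothed
discrete second derivative `y[i+1] − 2y[i] + y[i−1]`, and the mixture is
fitted by bounded nonlinear least squares with each `μ_k` confined to its
seed ± 1% of the entire profile length, and `σ_k`, `h_k` positive. Each
fitted peak's area is `h_k·σ_k·√(2π)`.

## Worked example

Six synthetic profiles — three "mammalian" replicates and three "runoff"
replicates in which stalled initiation has halved the polysome peaks — are
generated, written as instrument-style text files, re-imported, baselined
at the end of the profile, quantified and summarized:

```python
from polyquant import (recipe, generate, dialect, write_fixture, read_profile,
                       baseline_from_index, Region, quantify_profile,
                       relative_area, summarize, summary_table)

dia = dialect("peaktrak")
results, conditions = [], {}
for cond in ("control", "runoff"):
    for rep in range(3):
        rec = recipe("mammalian" if cond == "control" else "runoff",
                     rng_seed=10 * rep + (0 if cond == "control" else 5))
        profile, truth = generate(rec)
        pid = f"{cond}_{rep + 1}"
        profile.id = pid
        path = write_fixture(profile, dia, f"/tmp/{pid}.txt")
        p = read_profile(path, dia, id=pid)
        p.set_baseline(baseline_from_index(p.uv, len(p) - 26, 51))
        results += quantify_profile(p, [
            Region("Total", truth.total_region.start, truth.total_region.end),
            Region("Polysomes", truth.polysome_region.start, truth.polysome_region.end),
        ])
        conditions[pid] = cond
results = relative_area(results, "Polysomes", "Total")
print(summary_table(summarize(results, conditions)).to_string(index=False))
```

```
condition region_label channel relative_to       mean       sd  n
  control    Polysomes      uv       Total   0.694906 0.000765  3
  control        Total      uv             276.987273 6.638852  3
   runoff    Polysomes      uv       Total   0.532083 0.002544  3
   runoff        Total      uv             179.012650 2.332474  3
```

The control replicates put 69.5% of the total area in polysomes and the
run-off replicates 53.2% — against generator ground truth of 0.6931 and
0.5304, i.e. recovery well within 1%. Deconvolving the subunit region of
one control profile (40S leading flank to 80S trailing flank) resolves the
three overlapping peaks:

```python
from polyquant import seed_peaks, fit_gaussians
ctrl, truth = generate(recipe("mammalian", rng_seed=0))
b = baseline_from_index(ctrl.uv, len(ctrl) - 26, 51)
seeds = seed_peaks(ctrl.uv, b, smoothing=11, res=25, region=truth.deconvolution_region)
fit = fit_gaussians(ctrl.uv, b, truth.deconvolution_region, seeds)
print(fit.summary())
```

```
Gaussian deconvolution of region 'Subunits' [160, 336]
  peaks: 3   rss: 0.165398   converged: True   position tolerance: +/-10
  peak   seed         mu      sigma     height         area
     1    182    179.745     10.341     0.5038        13.06
     2    237    240.177     11.323     0.6983        19.82
     3    309    310.045     13.013      1.608       52.453
```

(True analytic areas: 12.53, 19.30, 52.14.) The same workflow is available
from the shell — `polyquant simulate`, `quantify`, `align`, `deconvolve`,
`summarize`, `session export|run`; every command writes its resolved
parameters to a `.log.yaml` next to its output, and `session run` replays a
saved analysis byte-identically.

## Scope

polyquant does not do correlation-optimized warping (profiles are only
shifted, stretched or shrunk by constant factors), statistical hypothesis
testing between conditions, multiple fluorescence channels, or multi-profile
input files. See `docs/methods.md` for the model details, parameter
defaults and known limitations.
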