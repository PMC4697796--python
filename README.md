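# focipair

Spatial point-pattern analysis of paired recombinase foci in meiotic
nuclei, with synthetic widefield and dSTORM data generators.

## The problem

During meiotic recombination in budding yeast, the RecA-family strand
exchange proteins Rad51 and Dmc1 assemble on the resected single-strand
tails of programmed DNA double-strand breaks (DSBs) and appear as
immunostained foci on spread nuclei. Two structural questions drive the
analyses here:

1. **Are foci arranged in pairs?** If the two ends of one DSB separate
   by up to ~400 nm and each end carries recombinase, foci should occur
   in pairs more often than expected for randomly placed foci.
2. **How large are the underlying filaments?** Super-resolution (dSTORM)
   imaging resolves each widefield focus into one or more "sr foci"
   whose dimensions, after correcting for antibody/optics broadening,
   bound the nucleoprotein filament length in nucleotides and protomers.

The package is aimed at microscopists and quantitative biologists who
score focus centroids (or simulate them) and need the pairing
statistics, classification rules and localization-microscopy diagnostics
behind those questions, without access to the original micrographs.

## The statistics

**Nearest-neighbor (NN) enrichment.** For each focus, the distance to
its nearest neighbor (same channel, or the other channel) is measured
and pooled over nuclei into a histogram with 50 nm bins. A *matched
null* places the same number of foci uniformly at random within each
nucleus's area (complete spatial randomness, CSR) and repeats the
measurement; by default the null also passes through the ~150 nm
*resolution censor* that merges foci the widefield assay cannot
separate. With observed and null bin fractions `f_obs(b)` and
`f_null(b)`, the per-bin excess is `f_obs − f_null` and the paired
fraction estimate is

    p̂ = Σ_{b : upper(b) ≤ 400 nm} max(0, f_obs(b) − f_null(b))

**Structure categories.** Mutual cross-channel nearest neighbors closer
than 200 nm merge into co-foci ("composites"); single-linkage clusters
of composites at 1 µm are "complexes"; each nucleus is classified I–V
(single focus / pair / >2 foci per channel / distant complexes with ≤2
per channel / distant with >2), with NEGATIVE for empty nuclei.

**dSTORM.** A two-state blinking simulator produces frame stacks with
ground truth; the localizer takes Gaussian-smoothed local maxima above
an SNR threshold, assigns intensity-weighted centroids and
second-moment widths, and rejects events wider than a FWHM cutoff
(default 2 pixels). Two simultaneously blinking emitters several
hundred nm apart are otherwise called as a single wide "event" near
their photon-weighted midpoint — the mis-localization artifact that the
width cutoff suppresses, quantified by `artifact_decay_curve`.

**Filament geometry.** With an apparent sr-focus length `L`,
broadening `b = 60 nm`, and 2 nt per nm:

    core = L − b,  nt = 2·core,  protomers = ⌊nt/3⌋,  turns = protomers/6.6

## Worked example

```python
import numpy as np
from focipair import (
    AnalysisConfig, PairModelParams, make_nucleus, simulate_dsb_pattern,
    apply_resolution_censor, nn_distances, nn_histogram,
    simulate_matched_null, pairing_enrichment, FocusSet, estimate_filament,
)

rng = np.random.default_rng(1)
params = PairModelParams(n_dsb=12, n_background_per_channel=4)
pooled = None
for i in range(20):
    part = simulate_dsb_pattern(make_nucleus(60.0, nucleus_id=f"n{i}"), params, seed=rng)
    pooled = part if pooled is None else pooled.concat(part)
observed = apply_resolution_censor(pooled)
rad51 = FocusSet(observed.df[observed.df.channel == "RAD51"].copy(),
                 nuclei=observed.nuclei)
hist = nn_histogram(nn_distances(rad51))
null = simulate_matched_null(rad51, reps=50, seed=2)
enr = pairing_enrichment(hist, null)
print(f"paired fraction estimate: {enr.paired_fraction_estimate:.3f}")

est = estimate_filament(114.0)
print(f"core {est.core_length_nm:.0f} nm -> {est.nt:.0f} nt, "
      f"{est.protomers} protomers, {est.turns:.1f} turns, "
      f"{est.tract_fraction_pct:.1f}% of an 800 nt tract")
```

prints

```
paired fraction estimate: 0.416
core 54 nm -> 108 nt, 36 protomers, 5.5 turns, 13.5% of an 800 nt tract
```

The paired-fraction estimate says that about 41% of Rad51 foci in this
simulated world carry a partner within 400 nm beyond what random
placement explains (the generative occupancy puts a focus pair at most
DSBs, diluted by background foci and censoring). The filament line
reads a 114 nm sr focus as a ~54 nm filament core: ~108 nt of ssDNA,
36 protomers, about five helical turns — under 15% of a typical 800 nt
resected tract.

The same stages are exposed on the command line:

```sh
focipair simulate --n-dsb 12 --n-nuclei 20 --seed 1 --out-foci foci.tsv
focipair nn --foci foci.tsv --area-um2 60 --seed 2 --out-hist hist.tsv
focipair filament --apparent-nm 114
focipair run --config demo.toml --out results/
```

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computations from
scratch — the paired-end simulation with NN enrichment against its
matched null, co-focus composition, per-nucleus categories, the
two-cluster blink simulation with the width-cutoff artifact decay, and
the filament chain — seeded entirely from `--seed`, and writes its
report to `--out`:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/focipair/model.py` — domain types, TSV/TIFF I/O, coordinate conventions
- `src/focipair/synthetic.py` — nuclei, DSB pairing patterns, CSR, censor, widefield renderer, blink simulator
- `src/focipair/nnstats.py` — NN distributions, matched CSR nulls, enrichment, density/sparseness filters, detectability bound
- `src/focipair/cofocus.py` — co-focus merging, pair detection/composition, intensity shares, category classifier, landmark selection
- `src/focipair/dstorm.py` — localizer, reconstruction, artifact diagnostic, sr-focus clustering/ellipses, filament geometry, blur congruence
- `src/focipair/cli.py`, `pipeline.py`, `report.py` — the `focipair` command, TOML-driven pipeline, run summaries

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
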