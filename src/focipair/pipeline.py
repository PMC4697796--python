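"""End-to-end pipeline: simulate -> nn -> cofocus -> vde -> storm.

A single run configuration (flat TOML sections) drives the stages; one
master seed is split per stage with :class:`numpy.random.SeedSequence`
so each stage is independently reproducible.  Outputs are deterministic
under a fixed (config, seed).
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .cofocus import (
    classify_nuclei,
    cross_fraction_within,
    detect_pairs,
    pair_composition_fraction,
    pair_intensity_shares,
)
from .dstorm import artifact_decay_curve, cluster_localizations, fit_ellipse
from .model import FocusSet, read_focus_table, write_focus_table
from .nnstats import nn_distances, nn_histogram, pairing_enrichment, simulate_matched_null
from .report import make_report, render_text_report
from .synthetic import (
    EmitterModel,
    PairModelParams,
    apply_resolution_censor,
    make_nucleus,
    simulate_blink_stack,
    simulate_dsb_pattern,
    uniform_sampler,
)

__all__ = ["run_pipeline", "KNOWN_KEYS"]

_STAGES = ("simulate", "nn", "cofocus", "vde", "storm")

KNOWN_KEYS = {
    None: {"seed", *_STAGES},
    "simulate": {
        "n_nuclei", "n_dsb", "n_background", "area_um2", "sep_min_nm", "sep_max_nm",
        "offset_max_nm", "p_both", "p_rad51_only", "p_dmc1_only", "p_empty", "censor",
    },
    "nn": {"channel", "null_reps", "censor", "foci"},
    "cofocus": {"foci"},
    "vde": {"foci"},
    "storm": {"n_frames", "separation_nm", "p_on", "photons_mean", "psf_sigma_nm",
              "background_rate"},
}


def _check_keys(config: dict) -> None:
    unknown = [k for k in config if k not in KNOWN_KEYS[None]]
    for stage in _STAGES:
        if stage in config:
            if not isinstance(config[stage], dict):
                raise ValueError(f"config section [{stage}] must be a table")
            unknown += [f"{stage}.{k}" for k in config[stage] if k not in KNOWN_KEYS[stage]]
    if unknown:
        raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")


def _nn_table(enrichment, observed, null) -> pd.DataFrame:
    lo = observed.bin_edges[:-1]
    hi = observed.bin_edges[1:]
    mc = enrichment.mc_se[:-1] if enrichment.mc_se is not None else np.full(len(lo), np.nan)
    return pd.DataFrame(
        {
            "bin_lo_nm": lo,
            "bin_hi_nm": hi,
            "observed_fraction": observed.fractions[:-1],
            "null_fraction": null.fractions[:-1],
            "excess": enrichment.excess[:-1],
            "mc_se": mc,
        }
    )


def run_pipeline(config: dict, out_dir: str | Path, seed: int | None = None) -> dict:
    """Execute the configured stages and emit tables plus a summary.

    Returns the report dict; writes ``summary.json``, ``summary.txt``
    and per-stage TSVs under ``out_dir``.
    """
    _check_keys(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.get("seed", seed)
    streams = {name: s for name, s in zip(_STAGES, np.random.SeedSequence(seed or 0).spawn(5))}
    analysis = AnalysisConfig(rng_seed=seed)
    outputs: dict[str, dict] = {}
    foci: FocusSet | None = None

    if "simulate" in config:
        c = config["simulate"]
        rng = np.random.default_rng(streams["simulate"])
        params = PairModelParams(
            n_dsb=int(c.get("n_dsb", 10)),
            n_background_per_channel=int(c.get("n_background", 0)),
            pair_sep_sampler=uniform_sampler(
                float(c.get("sep_min_nm", 150.0)), float(c.get("sep_max_nm", 400.0))
            ),
            cofocus_offset_sampler=uniform_sampler(0.0, float(c.get("offset_max_nm", 150.0))),
            occupancy=(
                float(c.get("p_both", 0.7)),
                float(c.get("p_rad51_only", 0.1)),
                float(c.get("p_dmc1_only", 0.1)),
                float(c.get("p_empty", 0.1)),
            ),
        )
        sets = []
        for i in range(int(c.get("n_nuclei", 5))):
            nucleus = make_nucleus(float(c.get("area_um2", 25.0)), nucleus_id=f"n{i}")
            sets.append(simulate_dsb_pattern(nucleus, params, seed=rng))
        foci = sets[0]
        for s in sets[1:]:
            foci = foci.concat(s)
        if c.get("censor", True):
            observed = apply_resolution_censor(foci, analysis.resolution_censor_nm)
        else:
            observed = foci
        write_focus_table(foci, out / "foci_truth.tsv")
        write_focus_table(observed, out / "foci_observed.tsv")
        foci = observed
        outputs["simulate"] = {
            "n_nuclei": len(foci.nuclei),
            "n_foci": len(foci),
            "truth_table": "foci_truth.tsv",
            "observed_table": "foci_observed.tsv",
        }

    def _load_stage_foci(c: dict) -> FocusSet:
        if "foci" in c:
            return read_focus_table(c["foci"])
        if foci is None:
            raise ValueError("stage needs a 'foci' input or a prior simulate stage")
        return foci

    if "nn" in config:
        c = config["nn"]
        stage_foci = _load_stage_foci(c)
        channel = c.get("channel", "RAD51")
        sub = FocusSet(
            stage_foci.df[stage_foci.df["channel"] == channel].copy(), nuclei=stage_foci.nuclei
        )
        observed_hist = nn_histogram(nn_distances(sub), analysis, label=f"{channel} observed")
        null = simulate_matched_null(
            sub,
            reps=int(c.get("null_reps", 100)),
            censor=bool(c.get("censor", True)),
            config=analysis,
            seed=np.random.default_rng(streams["nn"]),
        )
        enrich = pairing_enrichment(observed_hist, null, analysis)
        _nn_table(enrich, observed_hist, null).to_csv(
            out / "nn_histogram.tsv", sep="\t", index=False
        )
        outputs["nn"] = {
            "channel": channel,
            "n_distances": int(observed_hist.n_total),
            "paired_fraction_estimate": enrich.paired_fraction_estimate,
            "pair_window_nm": analysis.pair_window_nm,
            "null_reps": enrich.n_reps,
            "histogram_table": "nn_histogram.tsv",
        }

    if "cofocus" in config:
        c = config["cofocus"]
        stage_foci = _load_stage_foci(c)
        rad51 = FocusSet(
            stage_foci.df[stage_foci.df["channel"] == "RAD51"].copy(), nuclei=stage_foci.nuclei
        )
        dmc1 = FocusSet(
            stage_foci.df[stage_foci.df["channel"] == "DMC1"].copy(), nuclei=stage_foci.nuclei
        )
        pairs = detect_pairs(stage_foci, analysis)
        frac_cc, table = pair_composition_fraction(pairs)
        shares = pair_intensity_shares(pairs)
        outputs["cofocus"] = {
            "rad51_near_dmc1_fraction": cross_fraction_within(
                rad51, dmc1, analysis.coloc_radius_nm
            ),
            "dmc1_near_rad51_fraction": cross_fraction_within(
                dmc1, rad51, analysis.coloc_radius_nm
            ),
            "n_pairs": len(pairs),
            "both_cofocus_fraction": frac_cc,
            "composition": table,
            "intensity_share_slope": shares["slope"],
        }

    if "vde" in config:
        c = config["vde"]
        stage_foci = _load_stage_foci(c)
        cats = classify_nuclei(stage_foci, analysis)
        cats.to_csv(out / "vde_categories.tsv", sep="\t", index=False)
        outputs["vde"] = {
            "category_counts": cats["category"].value_counts().to_dict(),
            "n_nuclei": len(cats),
            "categories_table": "vde_categories.tsv",
        }

    if "storm" in config:
        c = config["storm"]
        rng_seed = streams["storm"].generate_state(1)[0] % (2**31)
        sep = float(c.get("separation_nm", 300.0))
        model = EmitterModel(
            positions=np.array(
                [[1000.0 - sep / 2, 1000.0], [1000.0 + sep / 2, 1000.0]]
            ),
            p_on=float(c.get("p_on", 0.25)),
            photons_mean=float(c.get("photons_mean", 1000.0)),
            psf_sigma_nm=float(c.get("psf_sigma_nm", 70.0)),
            background_rate=float(c.get("background_rate", 5.0)),
            shape_px=(20, 20),
        )
        stack, truth = simulate_blink_stack(
            model, n_frames=int(c.get("n_frames", 1000)), seed=int(rng_seed)
        )
        curve = artifact_decay_curve(
            stack, (1000.0 - sep / 2, 1000.0), (1000.0 + sep / 2, 1000.0)
        )
        outputs["storm"] = {
            "n_frames": stack.n_frames,
            "cutoffs_px": [c if math.isfinite(c) else "inf" for c in curve.cutoffs_px],
            "midpoint_fraction": curve.midpoint_fraction,
            "cluster_intensity_ratio": curve.cluster_intensity_ratio,
            "n_localizations": curve.n_total,
        }

    report = make_report(outputs, config, seed)
    (out / "summary.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out / "summary.txt").write_text(render_text_report(report))
    return report
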