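"""Analysis configuration shared across the pipeline stages.

All lengths are expressed in nanometers.  The defaults encode the
operational thresholds of the widefield focus-pairing assay: foci are
considered paired when separated by at most 400 nm, cross-channel
partners colocalize when closer than 200 nm, and the observation floor
below which two widefield foci merge into a single detected focus is
about 150 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and binning used throughout the analysis.

    Parameters
    ----------
    pair_window_nm
        Maximum centroid separation for two composite foci to count as a
        pair (default 400 nm).
    coloc_radius_nm
        Cross-channel colocalization radius; a RAD51 and a DMC1 focus
        closer than this form a co-focus (default 200 nm, strict ``<``).
    resolution_censor_nm
        Minimum inter-focus distance resolvable in the widefield assay;
        closer same-channel foci merge into one (default 150 nm).
    cluster_link_nm
        Single-linkage distance defining a cytological complex
        (default 1000 nm).
    density_threshold_per_um2
        Focus density below which a nucleus counts as low density
        (default 0.8 foci per square micron, strict ``<``).
    nn_bin_width_nm, nn_max_nm
        Nearest-neighbor histogram binning: uniform right-open bins of
        ``nn_bin_width_nm`` covering ``[0, nn_max_nm)`` plus an overflow
        bin.
    rng_seed
        Optional seed recorded with stochastic runs.
    """

    pair_window_nm: float = 400.0
    coloc_radius_nm: float = 200.0
    resolution_censor_nm: float = 150.0
    cluster_link_nm: float = 1000.0
    density_threshold_per_um2: float = 0.8
    nn_bin_width_nm: float = 50.0
    nn_max_nm: float = 2000.0
    rng_seed: int | None = field(default=None)

    def __post_init__(self) -> None:
        for name in (
            "pair_window_nm",
            "coloc_radius_nm",
            "resolution_censor_nm",
            "cluster_link_nm",
            "density_threshold_per_um2",
            "nn_bin_width_nm",
            "nn_max_nm",
        ):
            value = getattr(self, name)
            if name == "coloc_radius_nm":
                if value < 0:
                    raise ValueError(f"{name} must be >= 0, got {value!r}")
            elif not value > 0:
                raise ValueError(f"{name} must be > 0, got {value!r}")
        if self.pair_window_nm < self.coloc_radius_nm:
            raise ValueError(
                "pair_window_nm must be >= coloc_radius_nm "
                f"({self.pair_window_nm} < {self.coloc_radius_nm})"
            )


DEFAULT_CONFIG = AnalysisConfig()
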