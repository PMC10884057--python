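"""F1-F2 vowel-space comparison of simulated tracts against references.

Reference formants: human /u/ means and SDs for adult males, adult
females and children (Peterson & Barney survey values), plus two
chimpanzee hoo fixtures.  The literature prints two slightly different
chimpanzee means (a summary-table version and a methods-text version);
both are preserved verbatim and the methods-text values
(F1 358.75 +/- 56.93, F2 896.25 +/- 133.04 Hz) are the default
comparison target.

"Overlap" with a reference is operationalised as both F1 and F2 lying
within one SD of the reference mean; "closest fit" defaults to Euclidean
distance in Hz on the (F1, F2) plane, with a per-SD-normalised variant
for the unequal spread of the two axes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from hootube.chimp_tract import SweepResult

_METRICS = ("euclidean_hz", "per_sd_normalized")


@dataclass(frozen=True)
class VowelReference:
    """Mean +/- SD formants of a reference vowel category."""

    label: str
    f1_mean: float
    f1_sd: float
    f2_mean: float
    f2_sd: float

    def __post_init__(self) -> None:
        if min(self.f1_mean, self.f2_mean) <= 0 or min(self.f1_sd, self.f2_sd) < 0:
            raise ValueError("reference means must be positive and SDs non-negative")


#: Built-in reference table. chimp_hoo carries the summary-table values;
#: chimp_hoo_methods the methods-text values.
REFERENCES: dict[str, VowelReference] = {
    r.label: r
    for r in (
        VowelReference("human_male_u", 307.36, 50.01, 875.97, 155.46),
        VowelReference("human_female_u", 377.86, 46.76, 960.57, 171.46),
        VowelReference("human_child_u", 432.37, 87.48, 1193.33, 274.61),
        VowelReference("chimp_hoo", 374.44, 67.02, 896.25, 133.04),
        VowelReference("chimp_hoo_methods", 358.75, 56.93, 896.25, 133.04),
    )
}

DEFAULT_REFERENCE = "chimp_hoo_methods"


def load_references_csv() -> pd.DataFrame:
    """The shipped reference CSV as a DataFrame (bit-exact fixture)."""
    with resources.files("hootube.data").joinpath("vowel_references.csv").open() as fh:
        return pd.read_csv(fh)


@dataclass(frozen=True)
class FitResult:
    """Best-fitting sweep configuration for one reference."""

    reference_label: str
    best_params: dict
    best_f1: float
    best_f2: float
    distance: float
    within_one_sd_f1: bool
    within_one_sd_f2: bool

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be >= 0")


def _distances(rows: pd.DataFrame, ref: VowelReference, metric: str) -> np.ndarray:
    d1 = rows["f1_hz"].to_numpy() - ref.f1_mean
    d2 = rows["f2_hz"].to_numpy() - ref.f2_mean
    if metric == "euclidean_hz":
        return np.hypot(d1, d2)
    if metric == "per_sd_normalized":
        return np.hypot(d1 / ref.f1_sd, d2 / ref.f2_sd)
    raise ValueError(f"unknown metric {metric!r}; choose from {_METRICS}")


def nearest_configuration(
    sweep: SweepResult,
    ref: VowelReference = REFERENCES[DEFAULT_REFERENCE],
    metric: str = "euclidean_hz",
) -> FitResult:
    """The non-flagged sweep row closest to the reference means.

    Ties are broken by smaller total length, then by enumeration order.
    """
    ok = sweep.ok
    if ok.empty:
        raise ValueError("sweep contains no successful rows")
    dist = _distances(ok, ref, metric)
    best = np.min(dist)
    tied = ok.index[dist <= best]  # exact ties only; float equality intended
    if len(tied) > 1:
        tied = sorted(tied, key=lambda i: (ok.loc[i, "total_length_cm"], i))
    row = ok.loc[tied[0]]
    return FitResult(
        reference_label=ref.label,
        best_params={
            "protrusion_length_cm": float(row["protrusion_length_cm"]),
            "sac_length_cm": float(row["sac_length_cm"]),
            "sac_area_cm2": float(row["sac_area_cm2"]),
            "lip_area_cm2": float(row["lip_area_cm2"]),
            "total_length_cm": float(row["total_length_cm"]),
        },
        best_f1=float(row["f1_hz"]),
        best_f2=float(row["f2_hz"]),
        distance=float(best),
        within_one_sd_f1=bool(abs(row["f1_hz"] - ref.f1_mean) <= ref.f1_sd),
        within_one_sd_f2=bool(abs(row["f2_hz"] - ref.f2_mean) <= ref.f2_sd),
    )


def overlap_report(
    sweep: SweepResult,
    refs: list[VowelReference] | None = None,
) -> pd.DataFrame:
    """Per-reference overlap counts plus sweep-wide formant minima.

    A configuration overlaps a reference when both formants lie within
    one SD of that reference's means.  Columns: label, n_within_one_sd,
    fraction_within_one_sd, min_f1_hz, min_f2_hz (the minima are global
    across the sweep, repeated per row for a self-contained table).
    """
    if refs is None:
        refs = list(REFERENCES.values())
    ok = sweep.ok
    if ok.empty:
        raise ValueError("sweep contains no successful rows")
    min_f1 = float(ok["f1_hz"].min())
    min_f2 = float(ok["f2_hz"].min())
    records = []
    for ref in refs:
        hits = (
            ((ok["f1_hz"] - ref.f1_mean).abs() <= ref.f1_sd)
            & ((ok["f2_hz"] - ref.f2_mean).abs() <= ref.f2_sd)
        )
        records.append(
            {
                "label": ref.label,
                "n_within_one_sd": int(hits.sum()),
                "fraction_within_one_sd": float(hits.mean()),
                "min_f1_hz": min_f1,
                "min_f2_hz": min_f2,
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=["label", "n_within_one_sd", "fraction_within_one_sd", "min_f1_hz", "min_f2_hz"],
    )


def scatter_export(sweep: SweepResult, path, refs: list[VowelReference] | None = None) -> None:
    """Simple F1-F2 scatter of the sweep with reference means overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if refs is None:
        refs = list(REFERENCES.values())
    ok = sweep.ok
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(ok["f2_hz"], ok["f1_hz"], s=3, alpha=0.3, label="simulations")
    for ref in refs:
        ax.errorbar(
            ref.f2_mean, ref.f1_mean, xerr=ref.f2_sd, yerr=ref.f1_sd,
            marker="o", capsize=3, label=ref.label,
        )
    ax.invert_xaxis()
    ax.invert_yaxis()
    ax.set_xlabel("F2 (Hz)")
    ax.set_ylabel("F1 (Hz)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
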