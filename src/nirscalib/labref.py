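"""Laboratory reference-value processing for stalk mechanical strength.

Rind penetrometer resistance (RPR, N·mm⁻² with a 1 mm² probe) is measured at
five positions per internode; the internode value is the mean of the three
readings left after dropping one maximum and one minimum. Breaking force (N)
records a single peak per replicate. Six biological replicates per genotype
are aggregated to a mean, sample SD, standard error (SD/√n) and a relative
deviation expressed as the replicate coefficient of variation (SD/mean·100).
The genotype-level mean is the reference value fed to NIRS calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

RPR = "RPR"
BREAKING_FORCE = "breaking_force"
N_RPR_POSITIONS = 5


@dataclass
class ReplicateRecord:
    """One biological replicate: its position peak force readings."""

    genotype: str
    trait: str
    internode: int
    replicate: int  # 1..6
    peaks: tuple[float, ...]  # 5 positions for RPR, 1 for breaking force

    def __post_init__(self) -> None:
        self.peaks = tuple(float(p) for p in self.peaks)
        if self.trait == RPR and len(self.peaks) != N_RPR_POSITIONS:
            raise DataError(f"RPR replicate needs {N_RPR_POSITIONS} position peaks, got {len(self.peaks)}")
        if self.trait == BREAKING_FORCE and len(self.peaks) != 1:
            raise DataError("breaking-force replicate carries a single peak reading")
        if any(p <= 0 for p in self.peaks):
            raise DataError("peak force readings must be strictly positive")

    def value(self) -> float:
        """Replicate-level value: trimmed mean for RPR, the single peak otherwise."""
        if self.trait == RPR:
            return reduce_rpr_positions(self.peaks)
        return self.peaks[0]


@dataclass
class GenotypeSummary:
    """Replicate aggregate for one genotype × trait."""

    genotype: str
    trait: str
    mean: float
    sd: float
    se: float
    relative_deviation: float  # replicate CV, % = SD/mean·100
    n_replicates: int


def reduce_rpr_positions(peaks) -> float:
    """Mean of the 3 readings left after removing one max and one min.

    Ties remove exactly one instance each (so 5 identical readings keep 3).
    """
    peaks = [float(p) for p in peaks]
    if len(peaks) != N_RPR_POSITIONS:
        raise DataError(f"expected {N_RPR_POSITIONS} position readings, got {len(peaks)}")
    trimmed = sorted(peaks)[1:-1]
    return float(np.mean(trimmed))


def aggregate_genotype(records: list[ReplicateRecord]) -> GenotypeSummary:
    """Aggregate one genotype's replicates to mean, SD, SE and relative deviation."""
    if len(records) < 2:
        raise DataError("need at least 2 replicates to aggregate a genotype")
    genotypes = {r.genotype for r in records}
    traits = {r.trait for r in records}
    if len(genotypes) != 1 or len(traits) != 1:
        raise DataError(
            f"aggregate_genotype got mixed genotypes {sorted(genotypes)} or traits {sorted(traits)}"
        )
    values = np.array([r.value() for r in records])
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return GenotypeSummary(
        genotype=records[0].genotype,
        trait=records[0].trait,
        mean=mean,
        sd=sd,
        se=sd / np.sqrt(len(values)),
        relative_deviation=100.0 * sd / mean,
        n_replicates=len(values),
    )


def summaries_to_reference(summaries: list[GenotypeSummary], units: str):
    """Genotype means as a ReferenceTable (the value NIRS calibrates against)."""
    from .spectra import ReferenceTable

    traits = {s.trait for s in summaries}
    if len(traits) != 1:
        raise DataError("summaries mix traits")
    return ReferenceTable(
        [s.genotype for s in summaries], traits.pop(), units,
        np.array([s.mean for s in summaries]),
    )


def trait_correlation(
    a: list[GenotypeSummary], b: list[GenotypeSummary], alpha: float = 0.01
) -> dict:
    """Pearson correlation of two traits on shared genotypes.

    Pairs by genotype id (intersection only); returns r, n, the two-sided
    t-test p-value and a significance flag at the given alpha (default 0.01).
    """
    am = {s.genotype: s.mean for s in a}
    bm = {s.genotype: s.mean for s in b}
    shared = sorted(set(am) & set(bm))
    if len(shared) < 3:
        raise DataError(f"trait correlation needs >= 3 shared genotypes, got {len(shared)}")
    x = np.array([am[g] for g in shared])
    y = np.array([bm[g] for g in shared])
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "n": len(shared), "p": float(p), "significant": bool(p < alpha)}


def descriptive_distribution(values, n_bins: int = 20) -> dict:
    """Summary statistics and a fixed-width histogram of a trait sample."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise DataError("descriptive_distribution got an empty input")
    if values.min() == values.max():
        counts = np.array([values.size])
        edges = np.array([values.min() - 0.5, values.max() + 0.5])
    else:
        counts, edges = np.histogram(values, bins=n_bins)
    return {
        "n": int(values.size),
        "min": float(values.min()),
        "max": float(values.max()),
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
        "bin_edges": edges,
        "bin_counts": counts,
    }


# ---------------------------------------------------------------------------
# CSV I/O: replicate table and genotype summaries
# ---------------------------------------------------------------------------

def read_replicates(path) -> list[ReplicateRecord]:
    """Read a replicate CSV: genotype,trait,internode,replicate,p1..p5."""
    df = pd.read_csv(path, dtype={"genotype": str})
    records = []
    peak_cols = [c for c in df.columns if c.startswith("p") and c[1:].isdigit()]
    for _, row in df.iterrows():
        peaks = tuple(row[c] for c in peak_cols if pd.notna(row[c]))
        records.append(
            ReplicateRecord(
                genotype=row["genotype"],
                trait=row["trait"],
                internode=int(row["internode"]),
                replicate=int(row["replicate"]),
                peaks=peaks,
            )
        )
    return records


def write_replicates(records: list[ReplicateRecord], path) -> None:
    width = max(len(r.peaks) for r in records)
    rows = []
    for r in records:
        row = {
            "genotype": r.genotype,
            "trait": r.trait,
            "internode": r.internode,
            "replicate": r.replicate,
        }
        for i in range(width):
            row[f"p{i + 1}"] = r.peaks[i] if i < len(r.peaks) else None
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def summaries_frame(summaries: list[GenotypeSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "genotype": [s.genotype for s in summaries],
            "trait": [s.trait for s in summaries],
            "mean": [s.mean for s in summaries],
            "sd": [s.sd for s in summaries],
            "se": [s.se for s in summaries],
            "relative_deviation_pct": [s.relative_deviation for s in summaries],
            "n_replicates": [s.n_replicates for s in summaries],
        }
    )
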