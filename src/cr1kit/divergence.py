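"""Per-copy divergence to family representatives and binned landscapes.

Divergence is measured from a free-end-gap global alignment of the copy to
its family centroid/representative: p is the proportion of differing
aligned sites (gaps excluded), corrected to a Jukes–Cantor distance
d = -3/4 ln(1 - 4p/3).  Landscapes are half-open histograms of d per
family, the conventional repeat-landscape view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .pairwise import global_align_stats, make_global_aligner

__all__ = [
    "DivergenceRecord",
    "Landscape",
    "jukes_cantor",
    "copy_divergence",
    "build_landscape",
]


@dataclass(frozen=True)
class DivergenceRecord:
    copy_id: str
    family_id: str
    p: float | None  # proportion of differing aligned sites (gap-excluded)
    d_jc: float | None  # Jukes–Cantor substitutions/site
    aligned_sites: int
    representative_id: str = ""  # audit trail: which sequence d is measured to
    rejected_reason: str | None = None

    @property
    def ok(self) -> bool:
        return self.rejected_reason is None


@dataclass
class Landscape:
    species_id: str
    bin_width: float
    bins: dict[tuple[str, int], int]  # (family_id, bin index) -> copy count

    @property
    def total(self) -> int:
        return sum(self.bins.values())

    def family_marginal(self, family_id: str) -> dict[int, int]:
        return {
            b: n for (fam, b), n in sorted(self.bins.items()) if fam == family_id
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "family_id": fam,
                "bin": b,
                "d_lo": b * self.bin_width,
                "d_hi": (b + 1) * self.bin_width,
                "count": n,
            }
            for (fam, b), n in sorted(self.bins.items())
        ]
        return pd.DataFrame(rows, columns=["family_id", "bin", "d_lo", "d_hi", "count"])


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor distance d = -3/4 ln(1 - 4p/3) for site difference p.

    Exact closed form; d(0) = 0 and d is strictly increasing on [0, 0.75).
    p >= 0.75 saturates the correction and raises; p < 0 is invalid.
    """
    if p < 0:
        raise ValueError(f"proportion of differing sites cannot be negative: {p}")
    if p >= 0.75:
        raise ValueError(
            f"p = {p} >= 0.75: Jukes–Cantor correction is saturated (undefined)"
        )
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def copy_divergence(
    copy_id: str,
    copy_seq: str,
    representative_seq: str,
    family_id: str = "unassigned",
    representative_id: str = "",
    min_sites: int = 50,
    aligner=None,
) -> DivergenceRecord:
    """Divergence of one copy to its family representative.

    Global alignment with free end gaps; p = mismatches over gap-free
    aligned columns.  Records with fewer than ``min_sites`` aligned sites
    are rejected (reason recorded) rather than silently dropped.
    """
    if not copy_seq or not representative_seq:
        raise ValueError("both sequences must be non-empty")
    if aligner is None:
        aligner = make_global_aligner()
    stats = global_align_stats(representative_seq, copy_seq, aligner)
    sites = 0 if stats is None else stats.aligned_sites
    if stats is None or sites < min_sites:
        return DivergenceRecord(
            copy_id=copy_id,
            family_id=family_id,
            p=None,
            d_jc=None,
            aligned_sites=sites,
            representative_id=representative_id,
            rejected_reason=f"aligned_sites {sites} < min_sites {min_sites}",
        )
    p = stats.mismatches / sites
    if p >= 0.75:
        return DivergenceRecord(
            copy_id=copy_id,
            family_id=family_id,
            p=p,
            d_jc=None,
            aligned_sites=sites,
            representative_id=representative_id,
            rejected_reason="jukes-cantor saturation (p >= 0.75)",
        )
    return DivergenceRecord(
        copy_id=copy_id,
        family_id=family_id,
        p=p,
        d_jc=jukes_cantor(p),
        aligned_sites=sites,
        representative_id=representative_id,
    )


def build_landscape(
    records: list[DivergenceRecord],
    species_id: str = "",
    bin_width: float = 0.01,
) -> Landscape:
    """Bin accepted records into a per-family divergence landscape.

    Bins are half-open [k*w, (k+1)*w); counts are conserved: the landscape
    total equals the number of accepted records.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    bins: dict[tuple[str, int], int] = {}
    for rec in records:
        if not rec.ok:
            continue
        b = int(rec.d_jc // bin_width)
        key = (rec.family_id, b)
        bins[key] = bins.get(key, 0) + 1
    return Landscape(species_id=species_id, bin_width=bin_width, bins=bins)


def plot_landscape(landscape: Landscape, path: str) -> None:
    """Stacked per-family histogram (optional report output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = landscape.to_frame()
    if df.empty:
        fig, ax = plt.subplots()
        ax.set_title(f"{landscape.species_id}: no records")
        fig.savefig(path)
        plt.close(fig)
        return
    pivot = df.pivot_table(index="bin", columns="family_id", values="count", fill_value=0)
    fig, ax = plt.subplots(figsize=(8, 4))
    bottom = None
    for fam in pivot.columns:
        ax.bar(
            pivot.index * landscape.bin_width,
            pivot[fam],
            width=landscape.bin_width * 0.9,
            bottom=bottom,
            label=fam,
        )
        bottom = pivot[fam] if bottom is None else bottom + pivot[fam]
    ax.set_xlabel("Jukes–Cantor distance to family representative")
    ax.set_ylabel("copies")
    ax.set_title(landscape.species_id)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
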