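"""Genetic map: interpolation between physical (bp) and genetic (cM) coordinates."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GeneticMap:
    """Piecewise-linear map per chromosome.

    ``points[chrom] = (pos_bp, cm)`` with both arrays strictly increasing in
    bp and non-decreasing in cM.  Queries outside the mapped range clamp to
    the terminal rate of zero (np.interp semantics).
    """

    points: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def uniform(cls, chrom_lengths: dict[str, int], rate_cm_per_mb: float) -> "GeneticMap":
        pts = {}
        for chrom, L in chrom_lengths.items():
            pos = np.array([0, L], dtype=float)
            cm = np.array([0.0, L / 1e6 * rate_cm_per_mb])
            pts[str(chrom)] = (pos, cm)
        return cls(pts)

    def _get(self, chrom: str):
        try:
            return self.points[str(chrom)]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genetic map") from None

    def cm_at(self, chrom: str, pos) -> np.ndarray:
        bp, cm = self._get(chrom)
        if np.any(np.diff(cm) < 0):
            raise ValueError(f"non-monotone genetic map on {chrom}")
        return np.interp(np.asarray(pos, dtype=float), bp, cm)

    def morgans_at(self, chrom: str, pos) -> np.ndarray:
        return self.cm_at(chrom, pos) / 100.0

    def bp_at(self, chrom: str, cm) -> np.ndarray:
        bp, c = self._get(chrom)
        return np.interp(np.asarray(cm, dtype=float), c, bp)

    def chrom_cm(self, chrom: str) -> float:
        bp, cm = self._get(chrom)
        return float(cm[-1])

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.lower() for c in df.columns]
        pts = {}
        for chrom, g in df.groupby("chrom"):
            g = g.sort_values("pos_bp")
            pts[str(chrom)] = (g["pos_bp"].to_numpy(float), g["cm"].to_numpy(float))
        return cls(pts)

    def to_tsv(self, path) -> None:
        rows = []
        for chrom, (bp, cm) in sorted(self.points.items()):
            for b, c in zip(bp, cm):
                rows.append((chrom, int(b), c))
        pd.DataFrame(rows, columns=["chrom", "pos_bp", "cm"]).to_csv(path, sep="\t", index=False)
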