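"""Weir & Cockerham (1984) Fst variance components from genotype matrices.

Per-site components a (among populations), b (among individuals within
populations) and c (within individuals) are returned so callers can form
either per-site estimates a/(a+b+c) or windowed ratio-of-averages
sum(a)/sum(a+b+c).
"""
from __future__ import annotations

import numpy as np

from .panel import MISSING, VariantPanel


def wc_components(panel: VariantPanel, group_a: str, group_b: str):
    """Per-site WC components for two groups.

    Returns (a, b, c, valid) arrays over sites; ``valid`` is False where
    either group has < 2 called diploids or the site is monomorphic across
    both groups (components undefined / uninformative).
    """
    out_a, out_b, out_c, valid = _wc_from_genotypes(
        panel.genotypes[:, panel.pop_mask(group_a)],
        panel.genotypes[:, panel.pop_mask(group_b)],
    )
    return out_a, out_b, out_c, valid


def _wc_from_genotypes(g1: np.ndarray, g2: np.ndarray):
    r = 2.0
    comp = []
    for g in (g1, g2):
        called = g != MISSING
        n = called.sum(axis=1).astype(float)                  # diploids called
        alt = np.where(called, g, 0).sum(axis=1).astype(float)
        het = np.where(called, g == 1, False).sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / (2.0 * n)
            h = het / n
        comp.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = comp
    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    mono = (pbar <= 0) | (pbar >= 1)
    valid = valid & ~mono & np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c, valid


def per_site_fst(panel: VariantPanel, group_a: str, group_b: str) -> np.ndarray:
    """Per-site WC Fst a/(a+b+c); NaN where undefined.  Negative estimates
    are reported as computed (not clamped)."""
    a, b, c, valid = wc_components(panel, group_a, group_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = a / (a + b + c)
    return np.where(valid & ((a + b + c) != 0), f, np.nan)


def ratio_of_averages(a: np.ndarray, b: np.ndarray, c: np.ndarray, mask: np.ndarray) -> float:
    """Windowed WC estimate sum(a)/sum(a+b+c) over masked sites."""
    if not mask.any():
        return float("nan")
    num = np.nansum(a[mask])
    den = np.nansum((a + b + c)[mask])
    return float(num / den) if den != 0 else float("nan")
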