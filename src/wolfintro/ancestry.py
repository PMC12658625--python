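"""Genome-wide dog ancestry: supervised admixture proportion, pedigree-class
assignment for recent hybrids, and D-statistics with block-jackknife errors.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .panel import MISSING, PopulationRef, VariantPanel

PEDIGREE_TEMPLATES = {
    "F1": (0.0, 1.0, 0.0),
    "BC1w": (0.0, 0.5, 0.5),
    "BC2w": (0.0, 0.25, 0.75),
    "BC3w": (0.0, 0.125, 0.875),
}


@dataclass
class AncestryEstimate:
    sample_id: str
    q_dog: float
    loglik: float
    identifiable: bool


@dataclass
class PedigreeClassification:
    triple: tuple[float, float, float]          # (hom_dog, het, hom_wolf)
    distances: dict[str, float]
    independent_distance: float
    best_class: str
    recent_admixture: bool


@dataclass
class DStatResult:
    p1: str
    p2: str
    p3: str
    p4: str
    d: float
    se: float
    z: float
    n_blocks: int
    n_sites: int


def supervised_admixture(
    panel: VariantPanel,
    refs: PopulationRef,
    sample_id: str,
    dog_group: str = "DOG",
    wolf_group: str = "WIT",
) -> AncestryEstimate:
    """Two-source maximum-likelihood ancestry proportion for one sample.

    Maximizes sum_sites [g log(pi) + (2-g) log(1-pi)] with
    pi = q f_DOG + (1-q) f_WOLF over q in [0,1], using pseudocount-smoothed
    reference frequencies.  The caller is responsible for excluding the
    focal sample from the references (see allele_freqs(exclude_samples=...)).
    """
    g_mat = panel.derived_dosage() if refs.derived else panel.genotypes
    g = g_mat[:, panel.sample_index(sample_id)].astype(float)
    fd = refs.smoothed(dog_group)
    fw = refs.smoothed(wolf_group)
    ok = (g != MISSING) & ~np.isnan(fd) & ~np.isnan(fw)
    g, fd, fw = g[ok], fd[ok], fw[ok]
    if len(g) == 0:
        raise ValueError("no informative sites for supervised ancestry")
    identifiable = bool(np.max(np.abs(fd - fw)) > 1e-9)

    def nll(q):
        pi = np.clip(q * fd + (1 - q) * fw, 1e-12, 1 - 1e-12)
        return -np.sum(g * np.log(pi) + (2 - g) * np.log(1 - pi))

    res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-8})
    q = float(res.x) if identifiable else 0.0
    return AncestryEstimate(sample_id=sample_id, q_dog=q, loglik=float(-res.fun),
                            identifiable=identifiable)


def ancestry_triple(track_states: np.ndarray) -> tuple[float, float, float]:
    """Paired-ancestry triple (hom_dog, het, hom_wolf) from assigned bin states.

    ``track_states``: int array with 0=WW, 1=WD, 2=DD, -1 unassigned.
    """
    assigned = track_states[track_states >= 0]
    if len(assigned) == 0:
        raise ValueError("no assigned bins")
    n = float(len(assigned))
    return (float((assigned == 2).sum() / n), float((assigned == 1).sum() / n),
            float((assigned == 0).sum() / n))


def classify_pedigree(triple: tuple[float, float, float]) -> PedigreeClassification:
    """Match an observed (hom_dog, het, hom_wolf) triple to hybrid pedigrees.

    Compares Euclidean distance to the F1/BC1w/BC2w/BC3w templates and to
    the "independent" Hardy–Weinberg triple at q = hom_dog + het/2; the
    sample is called recently admixed when some pedigree fits better than
    the independent expectation.
    """
    t = np.asarray(triple, dtype=float)
    if (t < 0).any():
        raise ValueError("triple entries must be >= 0")
    s = t.sum()
    if s > 0:
        t = t / s
    q = t[0] + t[1] / 2.0
    hwe = np.array([q * q, 2 * q * (1 - q), (1 - q) * (1 - q)])
    d_ind = float(np.linalg.norm(t - hwe))
    dists = {name: float(np.linalg.norm(t - np.asarray(tpl)))
             for name, tpl in PEDIGREE_TEMPLATES.items()}
    best = min(dists, key=dists.get)
    return PedigreeClassification(
        triple=tuple(t), distances=dists, independent_distance=d_ind,
        best_class=best, recent_admixture=dists[best] < d_ind,
    )


def _dstat_site_terms(p1, p2, p3, p4):
    num = (p1 - p2) * (p3 - p4)
    den = (p1 + p2 - 2 * p1 * p2) * (p3 + p4 - 2 * p3 * p4)
    return num, den


def dstat(
    refs: PopulationRef,
    p1: str,
    p2: str,
    p3: str,
    p4: str,
    block_size_bp: int = 5_000_000,
) -> DStatResult:
    """Frequency-based D-statistic with delete-one block-jackknife z-score.

    Positive D indicates excess sharing between P1 and P3 (equivalently P2
    and P4); |z| > 3 is the conventional significance rule.  Blocks are
    contiguous ``block_size_bp`` windows; blocks without informative sites
    are dropped.
    """
    f = [refs.freq(g) for g in (p1, p2, p3, p4)]
    ok = ~np.any([np.isnan(x) for x in f], axis=0)
    num, den = _dstat_site_terms(*(x[ok] for x in f))
    informative = den != 0
    num, den = num[informative], den[informative]
    if den.sum() == 0 or len(den) == 0:
        raise ValueError("no informative sites for D-statistic")
    chrom = refs.chrom[ok][informative]
    pos = refs.pos[ok][informative]
    d = float(num.sum() / den.sum())

    # block labels: chromosome x physical window
    blocks = np.array([f"{c}:{p // block_size_bp}" for c, p in zip(chrom, pos)], dtype=object)
    uniq = np.unique(blocks)
    if len(uniq) < 2:
        return DStatResult(p1, p2, p3, p4, d, float("nan"), float("nan"), len(uniq), int(len(den)))
    d_loo = []
    tot_num, tot_den = num.sum(), den.sum()
    for b in uniq:
        m = blocks == b
        dd = tot_den - den[m].sum()
        if dd == 0:
            continue
        d_loo.append((tot_num - num[m].sum()) / dd)
    d_loo = np.asarray(d_loo)
    B = len(d_loo)
    se = float(np.sqrt((B - 1) / B * np.sum((d_loo - d_loo.mean()) ** 2)))
    z = d / se if se > 0 else float("inf") if d != 0 else 0.0
    return DStatResult(p1, p2, p3, p4, d, se, float(z), B, int(len(den)))
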