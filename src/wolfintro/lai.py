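"""Local ancestry inference with a 3-state diploid HMM on fixed-size bins.

States are dog-allele dosages over the two haplotypes: WW (wolf/wolf),
WD (dog/wolf heterozygous) and DD (dog/dog).  Emissions per bin multiply,
over the SNPs in the bin, the probability of the observed genotype given
two independent haplotypes whose alt-allele probabilities come from the
dog and wolf reference frequencies.  Transitions are two independent
per-haplotype Markov chains that switch toward the stationary ancestry
proportions (q, 1-q) with probability 1 - exp(-tau * d) over the inter-bin
genetic distance d (Morgans); tau acts as a switch intensity in
generations.  (q, tau) are fitted by a likelihood grid search refined by
EM with a numerical M-step; posteriors come from forward-backward.

This is a genotype-level simplification of read-based local-ancestry
models: it assumes accurately called diploid genotypes (appropriate for
high-coverage data) and consumes only per-bin state calls downstream.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .genmap import GeneticMap
from .intervals import empty_intervals, sort_intervals
from .panel import MISSING, PopulationRef, VariantPanel

STATE_NAMES = ("WOLF", "DOGWOLF", "DOG")   # dosage 0, 1, 2
UNASSIGNED = -1


@dataclass
class HmmParams:
    q_init: float = 0.05
    tau_init: float = 10.0
    posterior_threshold: float = 0.9
    q_grid: tuple = (0.01, 0.05, 0.1, 0.2, 0.4)
    tau_grid: tuple = (1.0, 3.0, 10.0, 30.0, 100.0, 300.0)
    em_max_iter: int = 25
    em_tol: float = 1e-4
    fit: bool = True            # False decodes at (q_init, tau_init) as given


@dataclass
class AncestryTrack:
    sample_id: str
    bin_bp: int
    chrom: np.ndarray           # str per bin
    start: np.ndarray           # int per bin (0-based)
    end: np.ndarray             # int per bin (half-open)
    posterior: np.ndarray       # (n_bins, 3)
    state: np.ndarray           # int8: 0 WW, 1 WD, 2 DD, -1 unassigned
    q_hat: float
    tau_hat: float
    loglik: float
    threshold: float
    em_logliks: list[float] | None = None   # per-EM-iteration log-likelihoods

    @property
    def n_bins(self) -> int:
        return len(self.start)

    def dog_mask(self) -> np.ndarray:
        """Bins assigned DOG or DOGWOLF."""
        return (self.state == 1) | (self.state == 2)

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chrom, "start": self.start, "end": self.end})
        for i, name in enumerate(STATE_NAMES):
            df[f"p_{name}"] = self.posterior[:, i]
        df["state"] = [STATE_NAMES[s] if s >= 0 else "unassigned" for s in self.state]
        return df


# ---------------------------------------------------------------------------
# emissions / transitions
# ---------------------------------------------------------------------------

def _log_emissions(g, fd, fw):
    """(n_snps, 3) log P(genotype | dosage state) for observed genotypes."""
    fd = np.clip(fd, 1e-12, 1 - 1e-12)
    fw = np.clip(fw, 1e-12, 1 - 1e-12)
    g = g.astype(np.int64)
    probs = np.empty((len(g), 3))
    for a, f_pair in enumerate(((fw, fw), (fd, fw), (fd, fd))):
        fa, fb = f_pair
        p0 = (1 - fa) * (1 - fb)
        p1 = fa * (1 - fb) + fb * (1 - fa)
        p2 = fa * fb
        tab = np.stack([p0, p1, p2], axis=1)
        probs[:, a] = tab[np.arange(len(g)), g]
    return np.log(np.clip(probs, 1e-300, None))


def _transition_stack(d: np.ndarray, q: float, tau: float) -> np.ndarray:
    """(n_steps, 3, 3) diploid transition matrices for inter-bin distances d."""
    s = 1.0 - np.exp(-tau * d)
    w2d = s * q                      # wolf hap -> dog
    d2d = (1.0 - s) + s * q          # dog hap -> dog
    T = np.empty((len(d), 3, 3))
    T[:, 0, 0] = (1 - w2d) ** 2
    T[:, 0, 1] = 2 * w2d * (1 - w2d)
    T[:, 0, 2] = w2d**2
    T[:, 1, 0] = (1 - d2d) * (1 - w2d)
    T[:, 1, 2] = d2d * w2d
    T[:, 1, 1] = 1.0 - T[:, 1, 0] - T[:, 1, 2]
    T[:, 2, 0] = (1 - d2d) ** 2
    T[:, 2, 1] = 2 * d2d * (1 - d2d)
    T[:, 2, 2] = d2d**2
    return T


def _stationary(q: float) -> np.ndarray:
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])


def _forward_backward(log_e: np.ndarray, T: np.ndarray, pi: np.ndarray):
    """Scaled forward-backward on one chain.

    Returns (loglik, gamma, xi) with gamma (n, 3) posteriors and xi
    (n-1, 3, 3) expected transition counts.
    """
    n = log_e.shape[0]
    e = np.exp(log_e - log_e.max(axis=1, keepdims=True))
    logc_extra = log_e.max(axis=1)
    alpha = np.empty((n, 3))
    c = np.empty(n)
    a = pi * e[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for k in range(1, n):
        a = (alpha[k - 1] @ T[k - 1]) * e[k]
        c[k] = a.sum()
        alpha[k] = a / c[k]
    beta = np.empty((n, 3))
    beta[-1] = 1.0
    for k in range(n - 2, -1, -1):
        beta[k] = (T[k] @ (e[k + 1] * beta[k + 1])) / c[k + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    if n > 1:
        xi = (alpha[:-1, :, None] * T * (e[1:] * beta[1:])[:, None, :]) / c[1:, None, None]
        xi /= xi.sum(axis=(1, 2), keepdims=True)
    else:
        xi = np.zeros((0, 3, 3))
    loglik = float(np.log(c).sum() + logc_extra.sum())
    return loglik, gamma, xi


def _forward_loglik(log_e, T, pi) -> float:
    n = log_e.shape[0]
    e = np.exp(log_e - log_e.max(axis=1, keepdims=True))
    a = pi * e[0]
    ll = np.log(a.sum())
    a = a / a.sum()
    for k in range(1, n):
        a = (a @ T[k - 1]) * e[k]
        s = a.sum()
        ll += np.log(s)
        a /= s
    return float(ll + log_e.max(axis=1).sum())


# ---------------------------------------------------------------------------
# binning and fitting
# ---------------------------------------------------------------------------

def _chrom_bins(panel: VariantPanel, bin_bp: int):
    """Per-chromosome bin grids and SNP->bin assignment."""
    chroms = sorted(set(map(str, panel.chrom)))
    out = []
    for chrom in chroms:
        m = panel.chrom == chrom
        L = panel.chrom_lengths.get(chrom, int(panel.pos[m].max()) + 1)
        n_bins = int(np.ceil(L / bin_bp))
        snp_bin = (panel.pos[m] // bin_bp).astype(np.int64)
        out.append((chrom, L, n_bins, np.flatnonzero(m), snp_bin))
    return out


def infer_local_ancestry(
    panel: VariantPanel,
    refs: PopulationRef,
    sample_id: str,
    bin_bp: int = 10_000,
    gmap: GeneticMap | None = None,
    params: HmmParams | None = None,
    dog_group: str = "DOG",
    wolf_group: str = "WIT",
) -> AncestryTrack:
    """Decode one individual's per-bin dog/wolf ancestry.

    The focal sample must already be excluded from ``refs`` (leave-one-out);
    smoothed reference frequencies are used throughout.
    """
    params = params or HmmParams()
    if gmap is None:
        raise ValueError("a genetic map is required")
    # genotype coding must match the reference-frequency coding
    g_mat = panel.derived_dosage() if refs.derived else panel.genotypes
    g_all = g_mat[:, panel.sample_index(sample_id)]
    fd_all = refs.smoothed(dog_group)
    fw_all = refs.smoothed(wolf_group)

    chains = []   # (chrom, n_bins, starts, log_e (n_bins,3), d (n_bins-1,))
    for chrom, L, n_bins, snp_idx, snp_bin in _chrom_bins(panel, bin_bp):
        g = g_all[snp_idx]
        fd, fw = fd_all[snp_idx], fw_all[snp_idx]
        ok = (g != MISSING) & ~np.isnan(fd) & ~np.isnan(fw)
        log_e = np.zeros((n_bins, 3))
        if ok.any():
            le = _log_emissions(g[ok], fd[ok], fw[ok])
            for s in range(3):
                np.add.at(log_e[:, s], snp_bin[ok], le[:, s])
        starts = np.arange(n_bins, dtype=np.int64) * bin_bp
        ends = np.minimum(starts + bin_bp, L)
        mids = (starts + ends) / 2.0
        d = np.diff(gmap.morgans_at(chrom, mids))
        if (d < 0).any():
            raise ValueError(f"non-monotone genetic map on {chrom}")
        d = np.maximum(d, 1e-12)
        chains.append((chrom, starts, ends, log_e, d))

    def loglik_at(q, tau):
        pi = _stationary(q)
        ll = 0.0
        for _, _, _, log_e, d in chains:
            ll += _forward_loglik(log_e, _transition_stack(d, q, tau), pi)
        return ll

    # grid initialization
    best = (-np.inf, params.q_init, params.tau_init)
    if params.fit:
        for q0 in set(params.q_grid) | {params.q_init}:
            for t0 in set(params.tau_grid) | {params.tau_init}:
                ll = loglik_at(q0, t0)
                if ll > best[0]:
                    best = (ll, q0, t0)
    _, q, tau = best
    em_logliks: list[float] = []
    prev_ll: float | None = None

    # EM refinement: E-step forward-backward, M-step numerical over (q, tau)
    for _ in range(params.em_max_iter if params.fit else 0):
        gammas, xis, ds = [], [], []
        ll_new = 0.0
        pi = _stationary(q)
        for _, _, _, log_e, d in chains:
            ll_c, gam, xi = _forward_backward(log_e, _transition_stack(d, q, tau), pi)
            ll_new += ll_c
            gammas.append(gam)
            xis.append(xi)
            ds.append(d)
        g1 = np.sum([gam[0] for gam in gammas], axis=0)
        xi_all = np.concatenate(xis, axis=0) if xis else np.zeros((0, 3, 3))
        d_all = np.concatenate(ds) if ds else np.zeros(0)

        def neg_q(theta):
            qq, tt = theta
            piq = np.clip(_stationary(qq), 1e-300, None)
            val = float(g1 @ np.log(piq))
            if len(d_all):
                T = np.clip(_transition_stack(d_all, qq, tt), 1e-300, None)
                val += float(np.sum(xi_all * np.log(T)))
            return -val

        em_logliks.append(ll_new)
        if prev_ll is not None and abs(ll_new - prev_ll) < params.em_tol:
            break
        prev_ll = ll_new
        res = minimize(neg_q, x0=[q, tau], method="L-BFGS-B",
                       bounds=[(1e-4, 1 - 1e-4), (1e-3, 1e4)])
        if -res.fun >= -neg_q([q, tau]):
            q, tau = float(res.x[0]), float(res.x[1])

    # final decode at fitted parameters
    pi = _stationary(q)
    chrom_out, start_out, end_out, post_out = [], [], [], []
    ll_final = 0.0
    for chrom, starts, ends, log_e, d in chains:
        ll_c, gam, _ = _forward_backward(log_e, _transition_stack(d, q, tau), pi)
        ll_final += ll_c
        chrom_out.extend([chrom] * len(starts))
        start_out.append(starts)
        end_out.append(ends)
        post_out.append(gam)
    posterior = np.vstack(post_out)
    state = np.where(posterior.max(axis=1) > params.posterior_threshold,
                     posterior.argmax(axis=1), UNASSIGNED).astype(np.int8)
    return AncestryTrack(
        sample_id=sample_id,
        bin_bp=bin_bp,
        chrom=np.asarray(chrom_out, dtype=object),
        start=np.concatenate(start_out),
        end=np.concatenate(end_out),
        posterior=posterior,
        state=state,
        q_hat=float(q),
        tau_hat=float(tau),
        loglik=float(ll_final),
        threshold=params.posterior_threshold,
        em_logliks=em_logliks or None,
    )


# ---------------------------------------------------------------------------
# tract extraction / sharing
# ---------------------------------------------------------------------------

def extract_tracts(track: AncestryTrack, states: tuple[int, ...] = (1, 2)) -> pd.DataFrame:
    """Merge maximal runs of assigned bins in the requested states into intervals."""
    sel = np.isin(track.state, list(states))
    if not sel.any():
        return empty_intervals(("sample", "mean_posterior"))
    rows = []
    i = 0
    n = track.n_bins
    while i < n:
        if not sel[i]:
            i += 1
            continue
        j = i
        while (j + 1 < n and sel[j + 1] and track.chrom[j + 1] == track.chrom[i]
               and track.start[j + 1] == track.end[j]):
            j += 1
        post = track.posterior[i : j + 1]
        mp = float(post[np.arange(j + 1 - i), track.state[i : j + 1]].mean())
        rows.append((track.chrom[i], int(track.start[i]), int(track.end[j]), track.sample_id, mp))
        i = j + 1
    return sort_intervals(pd.DataFrame(rows, columns=["chrom", "start", "end", "sample", "mean_posterior"]))


def _check_same_binning(tracks: list[AncestryTrack]) -> None:
    t0 = tracks[0]
    for t in tracks[1:]:
        if (t.bin_bp != t0.bin_bp or t.n_bins != t0.n_bins
                or not np.array_equal(t.start, t0.start)
                or not np.array_equal(t.chrom, t0.chrom)):
            raise ValueError("tracks are not on the same binning")


def shared_dog_regions(
    tracks_it: list[AncestryTrack],
    tracks_eu: list[AncestryTrack],
    top_pct: float = 10.0,
) -> pd.DataFrame:
    """Candidate historical introgressions: highly shared dog bins in Italian
    wolves that are absent (no dog state) in European wolves.

    A bin is eligible when its Italian sharing count reaches the
    (100 - top_pct) percentile of the positive sharing-count distribution
    (ties included) and no European track is in a dog state there.
    Strictly adjacent eligible bins merge into regions.
    """
    _check_same_binning(tracks_it + tracks_eu)
    t0 = tracks_it[0]
    counts = np.sum([t.dog_mask() for t in tracks_it], axis=0)
    eu = (np.sum([t.dog_mask() for t in tracks_eu], axis=0)
          if tracks_eu else np.zeros(t0.n_bins, dtype=int))
    positive = counts[counts > 0]
    if len(positive) == 0:
        return empty_intervals(("n_shared", "n_eu_dog"))
    thr = np.percentile(positive, 100.0 - top_pct)
    eligible = (counts >= thr) & (counts > 0) & (eu == 0)
    rows = []
    i, n = 0, t0.n_bins
    while i < n:
        if not eligible[i]:
            i += 1
            continue
        j = i
        while (j + 1 < n and eligible[j + 1] and t0.chrom[j + 1] == t0.chrom[i]
               and t0.start[j + 1] == t0.end[j]):
            j += 1
        rows.append((t0.chrom[i], int(t0.start[i]), int(t0.end[j]),
                     int(counts[i : j + 1].max()), int(eu[i : j + 1].max())))
        i = j + 1
    return sort_intervals(pd.DataFrame(rows, columns=["chrom", "start", "end", "n_shared", "n_eu_dog"]))


def query_locus(track: AncestryTrack, chrom: str, start: int, end: int) -> dict:
    """Per-bin states within an interval plus a dog-ancestry-present flag."""
    if end <= start:
        raise ValueError("empty interval")
    on = track.chrom == str(chrom)
    if not on.any():
        raise ValueError(f"chromosome {chrom} not decoded")
    chrom_end = int(track.end[on].max())
    if start < 0 or start >= chrom_end:
        raise ValueError(f"interval {chrom}:{start}-{end} off chromosome (length {chrom_end})")
    m = on & (track.end > start) & (track.start < end)
    idx = np.flatnonzero(m)
    present = bool(np.isin(track.state[idx], (1, 2)).any())
    return {
        "chrom": str(chrom),
        "start": int(start),
        "end": int(end),
        "bins": track.frame().iloc[idx].reset_index(drop=True),
        "dog_ancestry_present": present,
    }
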