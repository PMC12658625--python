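"""Genotype panels: containers, VCF input, site filters, polarization,
pairwise relatedness and per-population allele frequencies.

The in-memory representation is a :class:`VariantPanel`: a site table
(chrom, 0-based pos, ref, alt) plus a sites x samples genotype matrix coded
0/1/2 alt-allele dosage with -1 for missing, and optionally a phased
sites x (2*samples) haplotype matrix.  Population labels (e.g. DOG, WIT,
WEU, OUT) attach to samples.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1


@dataclass
class VariantPanel:
    samples: list[str]
    populations: np.ndarray          # str per sample
    chrom: np.ndarray                # str per site
    pos: np.ndarray                  # int64, 0-based, strictly increasing per chrom
    ref: np.ndarray                  # str per site
    alt: np.ndarray                  # str per site
    genotypes: np.ndarray            # (n_sites, n_samples) int8, -1 missing
    haplotypes: np.ndarray | None = None   # (n_sites, 2*n_samples) int8
    ancestral: np.ndarray | None = None    # int8 per site: 0 ref ancestral, 1 alt ancestral
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.populations = np.asarray(self.populations, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        g = self.genotypes
        bad = (g < -1) | (g > 2)
        if bad.any():
            raise ValueError("genotypes must be in {0,1,2} or -1 (missing)")

    # -- basic accessors -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in panel") from None

    def pop_mask(self, *labels: str) -> np.ndarray:
        return np.isin(self.populations, list(labels))

    def samples_in(self, *labels: str) -> list[str]:
        m = self.pop_mask(*labels)
        return [s for s, keep in zip(self.samples, m) if keep]

    def take_sites(self, mask_or_index) -> "VariantPanel":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            genotypes=self.genotypes[idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[idx],
            ancestral=None if self.ancestral is None else self.ancestral[idx],
        )

    def take_samples(self, sample_ids: list[str]) -> "VariantPanel":
        idx = np.array([self.sample_index(s) for s in sample_ids])
        hap = None
        if self.haplotypes is not None:
            hidx = np.column_stack([2 * idx, 2 * idx + 1]).ravel()
            hap = self.haplotypes[:, hidx]
        return replace(
            self,
            samples=list(sample_ids),
            populations=self.populations[idx],
            genotypes=self.genotypes[:, idx],
            haplotypes=hap,
        )

    def sample_haplotypes(self, sample_id: str) -> np.ndarray:
        if self.haplotypes is None:
            raise ValueError("panel is not phased")
        i = self.sample_index(sample_id)
        return self.haplotypes[:, 2 * i : 2 * i + 2]

    def derived_dosage(self) -> np.ndarray:
        """Genotypes recoded as derived-allele dosage (requires polarization)."""
        if self.ancestral is None:
            raise ValueError("panel is not polarized; call polarize() first")
        g = self.genotypes.astype(np.int8).copy()
        flip = self.ancestral == 1
        gg = g[flip]
        miss = gg == MISSING
        gg = 2 - gg
        gg[miss] = MISSING
        g[flip] = gg
        return g

    def sites_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "pos": self.pos, "ref": self.ref, "alt": self.alt})


@dataclass
class PopulationRef:
    """Per-site allele frequencies and called-allele counts for named groups.

    Frequencies refer to the alternate allele, or to the derived allele when
    built from a polarized panel (``derived=True``).  Sites with zero calls
    in a group carry NaN.
    """

    chrom: np.ndarray
    pos: np.ndarray
    freqs: dict[str, np.ndarray]
    counts: dict[str, np.ndarray]     # called alleles (2 x called diploids)
    derived: bool = False

    def groups(self) -> list[str]:
        return list(self.freqs)

    def freq(self, group: str) -> np.ndarray:
        return self.freqs[group]

    def smoothed(self, group: str) -> np.ndarray:
        """Pseudocount-smoothed frequency (x + 0.5) / (n + 1), never 0 or 1."""
        f, n = self.freqs[group], self.counts[group]
        x = np.where(np.isnan(f), 0.0, f) * n
        with np.errstate(invalid="ignore"):
            s = (x + 0.5) / (n + 1.0)
        return np.where(n > 0, s, 0.5)


@dataclass
class RelatednessRecord:
    sample_i: str
    sample_j: str
    king: float
    r0: float
    r1: float
    flag_related: bool
    insufficient: bool = False


# ---------------------------------------------------------------------------
# input
# ---------------------------------------------------------------------------

def read_sample_populations(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"], dtype=str)
    return dict(zip(df["sample"], df["population"]))


def read_panel(vcf_path, pops_path, chrom_allowlist: list[str] | None = None) -> VariantPanel:
    """Load a biallelic-SNP panel from VCF with per-sample population labels.

    Multi-allelic and non-SNP records are dropped (count logged).  An
    optional chromosome allow-list restricts to, e.g., autosomes.
    """
    from cyvcf2 import VCF

    labels = read_sample_populations(pops_path)
    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    unlabeled = [s for s in samples if s not in labels]
    if unlabeled:
        raise ValueError(f"samples missing population labels: {', '.join(unlabeled)}")

    allow = set(map(str, chrom_allowlist)) if chrom_allowlist is not None else None
    chroms, poss, refs, alts, gts, haps = [], [], [], [], [], []
    n_dropped = 0
    phased_all = True
    for v in vcf:
        if allow is not None and str(v.CHROM) not in allow:
            continue
        if len(v.ALT) != 1 or not v.is_snp:
            n_dropped += 1
            continue
        chroms.append(str(v.CHROM))
        poss.append(v.POS - 1)          # to 0-based
        refs.append(v.REF)
        alts.append(v.ALT[0])
        g = np.asarray(v.gt_types, dtype=np.int8)   # 0/1/2 alt dosage, 3 unknown
        g[g == 3] = MISSING
        gts.append(g)
        arr = v.genotype.array()        # (n_samples, 3): allele0, allele1, phased
        if not (arr[:, 2] > 0).all():
            phased_all = False
        h = arr[:, :2].astype(np.int8)
        h[h < 0] = MISSING
        haps.append(h.reshape(-1))
    if n_dropped:
        logger.info("read_panel: dropped %d multi-allelic/non-SNP records", n_dropped)
    if not poss:
        raise ValueError("no biallelic SNP records read from VCF")

    order = pd.DataFrame({"c": chroms, "p": poss}).sort_values(["c", "p"]).index.to_numpy()
    panel = VariantPanel(
        samples=samples,
        populations=np.array([labels[s] for s in samples], dtype=object),
        chrom=np.asarray(chroms, dtype=object)[order],
        pos=np.asarray(poss, dtype=np.int64)[order],
        ref=np.asarray(refs, dtype=object)[order],
        alt=np.asarray(alts, dtype=object)[order],
        genotypes=np.vstack(gts)[order],
        haplotypes=np.vstack(haps)[order] if phased_all else None,
        chrom_lengths={str(c): int(l) for c, l in zip(vcf.seqnames, vcf.seqlens)}
        if vcf.seqlens is not None and len(vcf.seqlens)
        else {},
    )
    panel.n_dropped_records = n_dropped
    return panel


# ---------------------------------------------------------------------------
# filtering / polarization
# ---------------------------------------------------------------------------

def apply_site_filters(
    panel: VariantPanel, min_call_rate: float = 0.0, min_maf: float = 0.0
) -> tuple[VariantPanel, dict[str, int]]:
    """Drop sites by call rate and minor-allele frequency; report removals."""
    for t in (min_call_rate, min_maf):
        if not 0.0 <= t <= 1.0:
            raise ValueError("thresholds must be in [0, 1]")
    g = panel.genotypes
    called = g != MISSING
    call_rate = called.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(called, g, 0).sum(axis=1) / (2.0 * called.sum(axis=1))
    maf = np.minimum(af, 1 - af)
    fail_cr = call_rate < min_call_rate
    # NaN maf (zero calls) only fails when a positive MAF threshold is set
    fail_maf = (maf < min_maf) | (np.isnan(maf) & (min_maf > 0))
    keep = ~(fail_cr | fail_maf)
    report = {
        "input_sites": panel.n_sites,
        "removed_call_rate": int(fail_cr.sum()),
        "removed_maf": int((fail_maf & ~fail_cr).sum()),
        "kept": int(keep.sum()),
    }
    if report["kept"] == 0:
        raise ValueError("all sites removed by filters; relax min_call_rate/min_maf")
    return panel.take_sites(keep), report


def polarize(panel: VariantPanel, outgroup_label: str = "OUT") -> VariantPanel:
    """Set the ancestral allele from the outgroup major allele.

    Sites where the outgroup is heterozygous, polymorphic across outgroup
    samples, or entirely missing are dropped: a small outgroup cannot
    resolve the ancestral state there.
    """
    om = panel.pop_mask(outgroup_label)
    if not om.any():
        raise ValueError(f"outgroup group {outgroup_label!r} is empty")
    og = panel.genotypes[:, om]
    called = og != MISSING
    n_called = called.sum(axis=1)
    alt_cnt = np.where(called, og, 0).sum(axis=1)
    # resolvable: every called outgroup genotype homozygous and concordant
    all_ref = (alt_cnt == 0) & (n_called > 0)
    all_alt = (alt_cnt == 2 * n_called) & (n_called > 0)
    keep = all_ref | all_alt
    out = panel.take_sites(keep)
    anc = np.zeros(out.n_sites, dtype=np.int8)
    anc[all_alt[keep]] = 1
    out.ancestral = anc
    return out


# ---------------------------------------------------------------------------
# relatedness
# ---------------------------------------------------------------------------

def _pair_counts(gi: np.ndarray, gj: np.ndarray) -> np.ndarray:
    """3x3 joint genotype counts over pairwise-complete sites."""
    ok = (gi != MISSING) & (gj != MISSING)
    a, b = gi[ok].astype(np.int64), gj[ok].astype(np.int64)
    return np.bincount(3 * a + b, minlength=9).reshape(3, 3)


def relatedness_from_counts(N: np.ndarray) -> tuple[float, float, float]:
    """KING-robust kinship and the Waples R0/R1 ratios from a 3x3 count table."""
    n11 = N[1, 1]
    n_opp = N[0, 2] + N[2, 0]
    het_i = N[1, :].sum()
    het_j = N[:, 1].sum()
    king = (n11 - 2.0 * n_opp) / (het_i + het_j) if (het_i + het_j) > 0 else np.nan
    r0 = n_opp / n11 if n11 > 0 else np.nan
    n_discordant = N.sum() - np.trace(N)
    if n_discordant > 0:
        r1 = n11 / n_discordant
    else:
        # no discordant genotypes at all: duplicates/identical twins
        r1 = np.inf if n11 > 0 else np.nan
    return float(king), float(r0), float(r1)


def pairwise_relatedness(
    panel: VariantPanel,
    king_min: float = 0.20,
    r0_max: float = 0.1,
    r1_min: float = 0.5,
    rule: str = "joint",
) -> list[RelatednessRecord]:
    """KING-robust kinship and R0/R1 for every sample pair.

    ``rule='joint'`` flags a pair related only when all three thresholds are
    crossed; ``rule='two_of_three'`` flags when at least two are.
    """
    if panel.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if rule not in ("joint", "two_of_three"):
        raise ValueError(f"unknown rule {rule!r}")
    g = panel.genotypes
    records = []
    for i in range(panel.n_samples):
        for j in range(i + 1, panel.n_samples):
            N = _pair_counts(g[:, i], g[:, j])
            king, r0, r1 = relatedness_from_counts(N)
            insufficient = N[1, 1] == 0
            hits = [
                not np.isnan(king) and king >= king_min,
                not np.isnan(r0) and r0 <= r0_max,
                not np.isnan(r1) and r1 >= r1_min,
            ]
            flag = all(hits) if rule == "joint" else sum(hits) >= 2
            records.append(
                RelatednessRecord(panel.samples[i], panel.samples[j], king, r0, r1,
                                  bool(flag and not insufficient), bool(insufficient))
            )
    return records


def relatedness_frame(records: list[RelatednessRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def merge_refs(*refs: PopulationRef) -> PopulationRef:
    """Combine group frequency tables computed on the same site grid
    (e.g. a focal-sample group plus leave-one-out population groups)."""
    first = refs[0]
    for r in refs[1:]:
        if not np.array_equal(r.pos, first.pos) or r.derived != first.derived:
            raise ValueError("refs must share the site grid and allele coding")
    freqs, counts = {}, {}
    for r in refs:
        freqs.update(r.freqs)
        counts.update(r.counts)
    return PopulationRef(chrom=first.chrom, pos=first.pos, freqs=freqs,
                         counts=counts, derived=first.derived)


def allele_freqs(
    panel: VariantPanel,
    group_names: list[str],
    exclude_samples: list[str] | None = None,
    derived: bool | None = None,
) -> PopulationRef:
    """Per-site alternate (or derived) allele frequency per named group.

    ``derived=None`` uses derived coding automatically when the panel is
    polarized.  ``exclude_samples`` supports leave-one-out references.  A
    group name that is not a population label but matches a sample id forms
    a single-sample group (per-individual D-statistic topologies).
    """
    if derived is None:
        derived = panel.ancestral is not None
    g = panel.derived_dosage() if derived else panel.genotypes
    excl = set(exclude_samples or ())
    freqs, counts = {}, {}
    for name in group_names:
        m = panel.pop_mask(name)
        if not m.any() and name in panel.samples:
            m = np.array([s == name for s in panel.samples])
        m = m & np.array([s not in excl for s in panel.samples])
        if not m.any():
            raise ValueError(f"group {name!r} has no (remaining) samples")
        gg = g[:, m]
        called = gg != MISSING
        n = 2.0 * called.sum(axis=1)
        x = np.where(called, gg, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n > 0, x / np.maximum(n, 1), np.nan)
        f[n == 0] = np.nan
        freqs[name] = f
        counts[name] = n
    return PopulationRef(chrom=panel.chrom, pos=panel.pos, freqs=freqs, counts=counts, derived=derived)
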