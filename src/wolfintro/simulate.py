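"""Synthetic dog/wolf/outgroup panels with known implanted dog-ancestry tracts.

Source populations are generated under a Balding–Nichols hierarchy: an
ancestral allele frequency per site, population frequencies beta-distributed
around it with a drift parameter F, and haplotype alleles Bernoulli in the
population frequency.  Drift parameters are derived from target pairwise
Fst values using the additivity of drift along branches and the Hudson
relation Fst ≈ F between two demes that each drifted F from a shared
ancestor:

    DOG   drifts F_d from the root
    WANC  drifts F_a from the root, then WIT and WEU each drift F_w/... see
    below; with F_w = fst_wolf_wolf and F_d = F_a = fst_dog_wolf - F_w/2,
    E[Fst(WIT, WEU)] = F_w and E[Fst(DOG, wolf)] = fst_dog_wolf.

The outgroup is monomorphic for the ancestral allele at every site.  Dog
ancestry is implanted into focal wolves as a Boolean (Poisson-start) tract
model on the genetic map: segment genetic lengths are exponential with mean
1/t Morgans (t = generations since admixture) and the start intensity is
chosen so the merged tracts cover an expected fraction q of the genome.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genmap import GeneticMap
from .intervals import empty_intervals, merge_intervals, sort_intervals, write_bed
from .panel import VariantPanel

POPULATIONS = ("DOG", "WIT", "WEU", "OUT")


@dataclass
class SimulationConfig:
    n_dog: int = 20
    n_wolf_it: int = 16
    n_wolf_eu: int = 13
    n_outgroup: int = 1
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"1": 50_000_000})
    n_sites: int = 5000
    fst_dog_wolf: float = 0.25
    fst_wolf_wolf: float = 0.05
    recomb_rate: float = 1.0        # cM/Mb
    seed: int = 0

    def __post_init__(self):
        for name in ("n_dog", "n_wolf_it", "n_wolf_eu", "n_outgroup"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        for name in ("fst_dog_wolf", "fst_wolf_wolf"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.fst_dog_wolf < self.fst_wolf_wolf / 2:
            raise ValueError("fst_dog_wolf must be >= fst_wolf_wolf / 2")

    def genetic_map(self) -> GeneticMap:
        return GeneticMap.uniform(self.chrom_lengths, self.recomb_rate)


@dataclass
class TractSpec:
    focal_ids: list[str]
    admix_time_gens: float = 5.0
    admix_fraction: float = 0.15
    haplotypes: tuple[int, ...] = (0, 1)             # which haplotypes receive tracts;
    #  (0,) gives backcross geometry: all dog ancestry on one haplotype
    explicit_intervals: pd.DataFrame | None = None   # chrom/start/end, applied to hap 0
    shared_haplotype: bool = False                   # draw the dog haplotype once per
    #  interval and copy it to every focal carrier (descent from one ancestor,
    #  the sweep-like geometry of a historical introgression)

    def __post_init__(self):
        if not 0.0 <= self.admix_fraction <= 1.0:
            raise ValueError("admix_fraction must be in [0, 1]")
        if self.admix_time_gens < 1:
            raise ValueError("admix_time_gens must be >= 1")
        if self.explicit_intervals is not None and len(self.explicit_intervals):
            iv = sort_intervals(self.explicit_intervals)
            same = iv["chrom"].to_numpy()[1:] == iv["chrom"].to_numpy()[:-1]
            if np.any(same & (iv["start"].to_numpy()[1:] < iv["end"].to_numpy()[:-1])):
                raise ValueError("explicit intervals overlap")


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    if f <= 0:
        return p.copy()
    # guard against exact 0/1 from an upstream drift stage
    p = np.clip(p, 1e-9, 1 - 1e-9)
    a = p * (1 - f) / f
    b = (1 - p) * (1 - f) / f
    return rng.beta(a, b)


def simulate_sources(config: SimulationConfig) -> VariantPanel:
    """Generate a phased DOG/WIT/WEU/OUT panel at the configured divergence.

    Deterministic under ``config.seed``.  The ancestral allele is REF at
    roughly half the sites and ALT at the rest, so polarization against the
    outgroup is exercised rather than trivial.
    """
    for name, pop in (("n_dog", "DOG"), ("n_wolf_it", "WIT"), ("n_outgroup", "OUT")):
        if getattr(config, name) == 0:
            raise ValueError(f"population {pop} requires at least one sample ({name}=0)")
    rng = np.random.default_rng(config.seed)

    # site placement proportional to chromosome length
    chroms = sorted(config.chrom_lengths, key=str)
    lens = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    n_per = rng.multinomial(config.n_sites, lens / lens.sum())
    site_chrom, site_pos = [], []
    for c, L, n in zip(chroms, lens, n_per):
        pos = np.sort(rng.choice(int(L), size=min(n, int(L)), replace=False))
        site_chrom.extend([str(c)] * len(pos))
        site_pos.extend(pos.tolist())
    site_chrom = np.asarray(site_chrom, dtype=object)
    site_pos = np.asarray(site_pos, dtype=np.int64)
    n_sites = len(site_pos)

    p_anc = rng.uniform(0.05, 0.95, size=n_sites)
    f_w = config.fst_wolf_wolf
    f_d = config.fst_dog_wolf - f_w / 2.0
    p_dog = _balding_nichols(rng, p_anc, f_d)
    p_wanc = _balding_nichols(rng, p_anc, f_d)
    p_wit = _balding_nichols(rng, p_wanc, f_w)
    p_weu = _balding_nichols(rng, p_wanc, f_w)

    counts = {"DOG": config.n_dog, "WIT": config.n_wolf_it, "WEU": config.n_wolf_eu, "OUT": config.n_outgroup}
    pfreq = {"DOG": p_dog, "WIT": p_wit, "WEU": p_weu}
    samples, pops, hap_cols = [], [], []
    for pop in POPULATIONS:
        for k in range(counts[pop]):
            samples.append(f"{pop}{k + 1}")
            pops.append(pop)
            if pop == "OUT":
                h = np.zeros((n_sites, 2), dtype=np.int8)   # ancestral; flipped below
            else:
                h = (rng.random((n_sites, 2)) < pfreq[pop][:, None]).astype(np.int8)
            hap_cols.append(h)
    hap = np.concatenate(hap_cols, axis=1)

    # choose which allele is labelled REF: ancestral at ~half the sites
    anc_is_alt = rng.random(n_sites) < 0.5
    hap[anc_is_alt] = 1 - hap[anc_is_alt]
    ref = np.where(anc_is_alt, "G", "A").astype(object)
    alt = np.where(anc_is_alt, "T", "C").astype(object)

    gt = hap[:, 0::2] + hap[:, 1::2]
    panel = VariantPanel(
        samples=samples,
        populations=np.asarray(pops, dtype=object),
        chrom=site_chrom,
        pos=site_pos,
        ref=ref,
        alt=alt,
        genotypes=gt.astype(np.int8),
        haplotypes=hap,
        chrom_lengths={str(c): int(config.chrom_lengths[c]) for c in chroms},
    )
    return panel


# ---------------------------------------------------------------------------
# tract implanting
# ---------------------------------------------------------------------------

def _random_tracts_one_hap(
    rng: np.random.Generator, gmap: GeneticMap, chrom: str, length_bp: int, q: float, t: float
) -> list[tuple[int, int]]:
    """Boolean tract model on one haplotype/chromosome in genetic coordinates."""
    if q <= 0:
        return []
    if q >= 1:
        return [(0, length_bp)]
    total_m = gmap.cm_at(chrom, length_bp) / 100.0
    rate = -t * np.log1p(-q)            # starts per Morgan
    # extend the start window left of the origin so coverage is stationary
    # across the whole chromosome (segments may begin before position 0)
    burn = 10.0 / t
    n_starts = rng.poisson(rate * (total_m + burn))
    if n_starts == 0:
        return []
    starts_m = np.sort(rng.uniform(-burn, total_m, size=n_starts))
    lengths_m = rng.exponential(1.0 / t, size=n_starts)
    ends_m = np.minimum(starts_m + lengths_m, total_m)
    keep = ends_m > 0
    starts_m, ends_m = np.maximum(starts_m[keep], 0.0), ends_m[keep]
    if len(starts_m) == 0:
        return []
    s_bp = gmap.bp_at(chrom, starts_m * 100.0).astype(np.int64)
    e_bp = np.ceil(gmap.bp_at(chrom, ends_m * 100.0)).astype(np.int64)
    e_bp = np.minimum(np.maximum(e_bp, s_bp + 1), length_bp)
    iv = [(int(s), int(e)) for s, e in zip(s_bp, e_bp) if e > s]
    # merge overlaps
    merged: list[tuple[int, int]] = []
    for s, e in iv:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def implant_tracts(
    panel: VariantPanel, spec: TractSpec, gmap: GeneticMap, seed: int
) -> tuple[VariantPanel, pd.DataFrame]:
    """Implant dog-ancestry segments into focal wolf haplotypes.

    Within each segment, the focal haplotype's alleles are redrawn as
    Bernoulli in the empirical dog allele frequency.  Returns the modified
    panel and the truth tract table (chrom/start/end/sample/hap, 0-based
    half-open bp).
    """
    if panel.haplotypes is None:
        raise ValueError("panel must be phased to implant tracts")
    for sid in spec.focal_ids:
        pop = panel.populations[panel.sample_index(sid)]
        if pop not in ("WIT", "WEU"):
            raise ValueError(f"focal sample {sid} is not a wolf (population {pop})")
    if spec.explicit_intervals is not None and len(spec.explicit_intervals):
        for _, row in spec.explicit_intervals.iterrows():
            L = panel.chrom_lengths.get(str(row["chrom"]))
            if L is None or row["start"] < 0 or row["end"] > L:
                raise ValueError(f"explicit interval {row['chrom']}:{row['start']}-{row['end']} outside chromosome bounds")

    rng = np.random.default_rng(seed)
    dogs = panel.pop_mask("DOG")
    gdog = panel.genotypes[:, dogs]
    called = gdog != -1
    with np.errstate(invalid="ignore"):
        f_dog = np.where(called, gdog, 0).sum(axis=1) / np.maximum(2.0 * called.sum(axis=1), 1)

    hap = panel.haplotypes.copy()
    truth_rows = []
    chrom_arr, pos_arr = panel.chrom, panel.pos
    shared_alleles: dict[tuple, np.ndarray] = {}
    for sid in spec.focal_ids:
        si = panel.sample_index(sid)
        for hidx in spec.haplotypes:
            if spec.explicit_intervals is not None:
                if hidx != spec.haplotypes[0]:
                    continue
                ivs = [(str(r["chrom"]), int(r["start"]), int(r["end"]))
                       for _, r in spec.explicit_intervals.iterrows()]
            else:
                ivs = []
                for chrom, L in panel.chrom_lengths.items():
                    for s, e in _random_tracts_one_hap(rng, gmap, chrom, L,
                                                       spec.admix_fraction, spec.admix_time_gens):
                        ivs.append((chrom, s, e))
            for chrom, s, e in ivs:
                m = (chrom_arr == chrom) & (pos_arr >= s) & (pos_arr < e)
                if m.any():
                    if spec.shared_haplotype:
                        key = (chrom, s, e)
                        if key not in shared_alleles:
                            shared_alleles[key] = (rng.random(int(m.sum()))
                                                   < f_dog[m]).astype(np.int8)
                        hap[m, 2 * si + hidx] = shared_alleles[key]
                    else:
                        hap[m, 2 * si + hidx] = (rng.random(int(m.sum()))
                                                 < f_dog[m]).astype(np.int8)
                truth_rows.append((chrom, s, e, sid, hidx))

    truth = (
        pd.DataFrame(truth_rows, columns=["chrom", "start", "end", "sample", "hap"])
        if truth_rows
        else empty_intervals(("sample", "hap"))
    )
    gt = hap[:, 0::2] + hap[:, 1::2]
    out = replace(panel, haplotypes=hap, genotypes=gt.astype(np.int8))
    return out, sort_intervals(truth)


def make_gene_annotations(
    chrom_lengths: dict[str, int],
    n_genes: int,
    size_range_bp: tuple[int, int],
    truth: pd.DataFrame,
    overlap_fraction: float,
    seed: int,
) -> pd.DataFrame:
    """Place non-overlapping gene intervals, a fraction fully inside truth tracts.

    Genes are named g0001.. and returned sorted.  Raises if the requested
    in-tract genes cannot fit inside any truth tract.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    lo, hi = size_range_bp
    n_inside = int(round(n_genes * overlap_fraction))
    tr = merge_intervals(truth) if len(truth) else empty_intervals()

    placed: dict[str, list[tuple[int, int]]] = {str(c): [] for c in chrom_lengths}

    def collides(chrom, s, e):
        return any(s < pe and ps < e for ps, pe in placed[chrom])

    genes = []
    # genes inside truth tracts
    if n_inside > 0:
        host = tr[(tr["end"] - tr["start"]) >= lo]
        if host.empty:
            raise ValueError("truth tracts too short to host a gene of the requested size")
        weights = (host["end"] - host["start"]).to_numpy(float)
        for k in range(n_inside):
            for _ in range(1000):
                row = host.iloc[rng.choice(len(host), p=weights / weights.sum())]
                span = int(row["end"] - row["start"])
                size = int(rng.integers(lo, min(hi, span) + 1))
                s = int(row["start"] + rng.integers(0, span - size + 1))
                if not collides(str(row["chrom"]), s, s + size):
                    placed[str(row["chrom"])].append((s, s + size))
                    genes.append((str(row["chrom"]), s, s + size))
                    break
            else:
                raise ValueError("could not place requested in-tract genes without overlap")
    # genes fully outside truth tracts
    chroms = sorted(chrom_lengths, key=str)
    lens = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    for k in range(n_genes - n_inside):
        for _ in range(10000):
            c = chroms[rng.choice(len(chroms), p=lens / lens.sum())]
            size = int(rng.integers(lo, hi + 1))
            if chrom_lengths[c] <= size:
                continue
            s = int(rng.integers(0, chrom_lengths[c] - size))
            e = s + size
            tt = tr[tr["chrom"] == str(c)]
            hits_truth = bool(((tt["start"] < e) & (s < tt["end"])).any()) if len(tt) else False
            if not hits_truth and not collides(str(c), s, e):
                placed[str(c)].append((s, e))
                genes.append((str(c), s, e))
                break
        else:
            raise ValueError("could not place genes outside truth tracts without overlap")
    df = pd.DataFrame(genes, columns=["chrom", "start", "end"])
    df = sort_intervals(df)
    df["name"] = [f"g{i + 1:04d}" for i in range(len(df))]
    return df


# ---------------------------------------------------------------------------
# fixture files
# ---------------------------------------------------------------------------

def write_vcf(panel: VariantPanel, path) -> None:
    """Write the panel as a minimal VCF 4.2 with phased GT."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, L in sorted(panel.chrom_lengths.items(), key=lambda kv: kv[0]):
            fh.write(f"##contig=<ID={chrom},length={L}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.samples) + "\n")
        hap = panel.haplotypes
        for i in range(panel.n_sites):
            if hap is not None:
                gts = [f"{hap[i, 2 * j]}|{hap[i, 2 * j + 1]}" for j in range(panel.n_samples)]
            else:
                code = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
                gts = [code[int(panel.genotypes[i, j])] for j in range(panel.n_samples)]
            fh.write(
                f"{panel.chrom[i]}\t{panel.pos[i] + 1}\t.\t{panel.ref[i]}\t{panel.alt[i]}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


def write_fixture(panel: VariantPanel, truth: pd.DataFrame, genes: pd.DataFrame,
                  gmap: GeneticMap, out_dir) -> dict[str, str]:
    """Emit VCF + labels TSV + truth/genes BED + genetic map TSV into out_dir."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "panel.vcf"),
        "populations": os.path.join(out_dir, "populations.tsv"),
        "truth_bed": os.path.join(out_dir, "truth_tracts.bed"),
        "genes_bed": os.path.join(out_dir, "genes.bed"),
        "genetic_map": os.path.join(out_dir, "genetic_map.tsv"),
    }
    write_vcf(panel, paths["vcf"])
    pd.DataFrame({"sample": panel.samples, "population": panel.populations}).to_csv(
        paths["populations"], sep="\t", header=False, index=False
    )
    if len(truth):
        tr = truth.copy()
        tr["name"] = tr["sample"].astype(str) + ":" + tr["hap"].astype(str)
        write_bed(tr, paths["truth_bed"], name_col="name")
    else:
        open(paths["truth_bed"], "w").close()
    write_bed(genes, paths["genes_bed"], name_col="name")
    gmap.to_tsv(paths["genetic_map"])
    return paths
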