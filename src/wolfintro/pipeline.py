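"""End-to-end scenarios: per-individual recent-introgression assessment and
the historical shared-introgression cascade (sharing filter, window-scan
validation, selection statistics, dating).

Both runners accept a :class:`PipelineConfig` (typically from YAML), write
TSV/BED/JSON outputs plus a manifest recording every parameter and the
seed, and return their reports as Python objects for library use.
"""
from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ancestry import classify_pedigree, dstat, supervised_admixture, ancestry_triple
from .dating import (GENERATION_TIME_YEARS, MUTATION_RATES, estimate_tmrca,
                     generations_to_years, haplotype_decay_lengths)
from .genmap import GeneticMap
from .intervals import write_bed
from .lai import HmmParams, extract_tracts, infer_local_ancestry, shared_dog_regions
from .panel import (VariantPanel, allele_freqs, merge_refs, pairwise_relatedness,
                    polarize, read_panel)
from .scan import validate_candidates, window_dstats, window_fst
from .selection import IhsOptions, flag_selection_outliers, ihs, ncd2, tajimas_d

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vcf: str = ""
    populations: str = ""
    genetic_map: str = ""
    genes_bed: str | None = None
    out_dir: str = "wolfintro_out"
    chrom_allowlist: list[str] | None = None
    # group labels
    dog: str = "DOG"
    wolf_it: str = "WIT"
    wolf_eu: str = "WEU"
    outgroup: str = "OUT"
    # stage parameters (defaults follow the published analysis settings)
    bin_bp: int = 10_000
    posterior_threshold: float = 0.9
    window_bp: int = 100_000
    step_bp: int = 10_000
    sel_window_bp: int = 50_000
    shared_top_pct: float = 10.0
    d_top_pct: float = 0.1
    fst_low_pct: float = 1.0
    sel_pct: float = 1.0
    fst_snp_threshold: float = 0.95
    n_shuffles: int = 1000
    admixed_q_min: float = 0.01
    # signals required before a validated region is dated: the default demands
    # a negative-Tajima outlier AND an iHS outlier (multiple concordant
    # signatures); "ihs" relaxes to the haplotype signal alone
    dating_signals: str = "tajima_and_ihs"
    mutation_rates: tuple[float, float] = MUTATION_RATES
    generation_time: float = GENERATION_TIME_YEARS
    recent_generations_max: int = 7     # labeling boundary recent vs historical
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        defaults = cls()
        for k in known:
            if getattr(cfg, k) != getattr(defaults, k):
                logger.info("config override: %s = %r", k, getattr(cfg, k))
        return cfg


def _manifest(cfg: PipelineConfig, stage: str) -> dict:
    d = asdict(cfg)
    d["wolfintro_version"] = __version__
    d["stage"] = stage
    return d


def _load(cfg: PipelineConfig):
    panel = read_panel(cfg.vcf, cfg.populations, cfg.chrom_allowlist)
    gmap = GeneticMap.from_tsv(cfg.genetic_map)
    return panel, gmap


def drop_related(panel: VariantPanel, rule: str = "joint") -> tuple[VariantPanel, list[str]]:
    """Remove one member of each flagged related pair (the later sample)."""
    records = pairwise_relatedness(panel, rule=rule)
    drop: set[str] = set()
    for r in records:
        if r.flag_related and r.sample_i not in drop and r.sample_j not in drop:
            drop.add(r.sample_j)
    keep = [s for s in panel.samples if s not in drop]
    return panel.take_samples(keep), sorted(drop)


def _lai_refs(panel, cfg, focal, wolf_groups):
    """Leave-one-out references with a combined wolf group for the HMM."""
    refs = allele_freqs(panel, [cfg.dog] + wolf_groups, exclude_samples=[focal])
    if len(wolf_groups) > 1:
        x = sum(np.nan_to_num(refs.freq(g)) * refs.counts[g] for g in wolf_groups)
        n = sum(refs.counts[g] for g in wolf_groups)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n > 0, x / np.maximum(n, 1), np.nan)
        refs.freqs["WOLFREF"] = f
        refs.counts["WOLFREF"] = n
        return refs, "WOLFREF"
    return refs, wolf_groups[0]


def run_recent(cfg: PipelineConfig) -> dict:
    """Scenario 1: per-Italian-wolf recent-introgression report.

    Relatedness filter -> supervised ancestry q (leave-one-out, dog vs
    non-admixed Italian references) -> pedigree class from the local-
    ancestry triple -> per-individual D-statistic -> local ancestry and
    tract BEDs.
    """
    stage = "load"
    try:
        panel, gmap = _load(cfg)
        stage = "relatedness"
        panel, dropped = drop_related(panel)
        stage = "polarize"
        panel = polarize(panel, cfg.outgroup)
        wits = panel.samples_in(cfg.wolf_it)
        if not wits:
            raise ValueError(f"no samples in group {cfg.wolf_it}")

        # pass 1: provisional q with all other Italian wolves as wolf reference
        stage = "supervised_q"
        q1 = {}
        for sid in wits:
            refs = allele_freqs(panel, [cfg.dog, cfg.wolf_it], exclude_samples=[sid])
            q1[sid] = supervised_admixture(panel, refs, sid, cfg.dog, cfg.wolf_it).q_dog
        admixed = [s for s in wits if q1[s] > cfg.admixed_q_min]
        nonadmixed = [s for s in wits if s not in admixed]

        # pass 2: non-admixed-only references
        stage = "per_individual"
        os.makedirs(cfg.out_dir, exist_ok=True)
        rows = []
        tracks = {}
        for sid in wits:
            excl = sorted(set(admixed) | {sid})
            if len(set(wits) - set(excl)) < 2:
                excl = [sid]
            refs = allele_freqs(panel, [cfg.dog, cfg.wolf_it, cfg.outgroup], exclude_samples=excl)
            est = supervised_admixture(panel, refs, sid, cfg.dog, cfg.wolf_it)
            ds_refs = merge_refs(allele_freqs(panel, [sid]), refs)
            ds = dstat(ds_refs, sid, cfg.wolf_it, cfg.dog, cfg.outgroup)
            track = infer_local_ancestry(
                panel, refs, sid, bin_bp=cfg.bin_bp, gmap=gmap,
                params=HmmParams(posterior_threshold=cfg.posterior_threshold),
                dog_group=cfg.dog, wolf_group=cfg.wolf_it)
            tracks[sid] = track
            try:
                ped = classify_pedigree(ancestry_triple(track.state))
                ped_class, recent = ped.best_class, ped.recent_admixture
            except ValueError:
                ped_class, recent = "NA", False
            tr = extract_tracts(track)
            write_bed(tr, os.path.join(cfg.out_dir, f"tracts_{sid}.bed"), name_col="sample")
            rows.append({
                "sample": sid, "q_dog": est.q_dog, "d": ds.d, "z": ds.z,
                "pedigree_class": ped_class, "recent_admixture": recent,
                "q_hat_hmm": track.q_hat, "n_dog_bins": int(track.dog_mask().sum()),
                "admixed": sid in admixed,
            })
        report = pd.DataFrame(rows)
        report.to_csv(os.path.join(cfg.out_dir, "recent_report.tsv"), sep="\t", index=False)
        with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
            json.dump({**_manifest(cfg, "recent"), "dropped_related": dropped}, fh, indent=2)
        return {"report": report, "tracks": tracks, "dropped_related": dropped,
                "admixed": admixed, "nonadmixed": nonadmixed}
    except Exception as exc:
        raise RuntimeError(f"run_recent failed at stage '{stage}': {exc}") from exc


def run_historical(cfg: PipelineConfig) -> dict:
    """Scenario 2: shared historical introgressions with validation,
    selection scans and dating."""
    stage = "load"
    try:
        panel, gmap = _load(cfg)
        stage = "relatedness"
        panel, dropped = drop_related(panel)
        stage = "polarize"
        panel = polarize(panel, cfg.outgroup)
        wits = panel.samples_in(cfg.wolf_it)
        weus = panel.samples_in(cfg.wolf_eu)
        if not wits:
            raise ValueError(f"no samples in group {cfg.wolf_it}")
        if not weus:
            raise ValueError(f"no samples in group {cfg.wolf_eu}")

        stage = "local_ancestry"
        hmm = HmmParams(posterior_threshold=cfg.posterior_threshold)
        tracks_it, tracks_eu = [], []
        for sid in wits + weus:
            refs, wolf_ref = _lai_refs(panel, cfg, sid, [cfg.wolf_it, cfg.wolf_eu])
            track = infer_local_ancestry(panel, refs, sid, bin_bp=cfg.bin_bp,
                                         gmap=gmap, params=hmm,
                                         dog_group=cfg.dog, wolf_group=wolf_ref)
            (tracks_it if sid in wits else tracks_eu).append(track)

        stage = "shared_regions"
        candidates = shared_dog_regions(tracks_it, tracks_eu, top_pct=cfg.shared_top_pct)

        stage = "window_scans"
        refs_all = allele_freqs(panel, [cfg.wolf_eu, cfg.wolf_it, cfg.dog, cfg.outgroup])
        dwin = window_dstats(refs_all, cfg.wolf_eu, cfg.wolf_it, cfg.dog, cfg.outgroup,
                             window_bp=cfg.window_bp, step_bp=cfg.step_bp,
                             chrom_lengths=panel.chrom_lengths)
        fwin = window_fst(panel, cfg.wolf_it, cfg.dog, group_c=cfg.wolf_eu,
                          window_bp=cfg.window_bp, step_bp=cfg.step_bp)
        validated = validate_candidates(candidates, dwin, fwin,
                                        d_pct=cfg.d_top_pct, fst_pct=cfg.fst_low_pct)

        stage = "selection"
        taj = tajimas_d(panel, cfg.wolf_it, window_bp=cfg.sel_window_bp)
        ncd = ncd2(panel, cfg.wolf_it, cfg.outgroup, tf=0.5, window_bp=cfg.sel_window_bp)
        taj, ncd = flag_selection_outliers(taj, ncd, pct=cfg.sel_pct)
        ihs_df = ihs(panel, gmap, cfg.wolf_it, IhsOptions(alpha=0.01, log_p_pct=cfg.sel_pct)) \
            if panel.haplotypes is not None else pd.DataFrame()

        stage = "dating"
        datings = []
        for _, reg in validated[validated["d_validated"]].iterrows():
            rsel = (taj["chrom"] == reg["chrom"]) & (taj["start"] < reg["end"]) & (reg["start"] < taj["end"])
            neg = bool((taj[rsel]["tajima_neg_outlier"] & (taj[rsel]["tajima_d"] < 0)).any())
            if ihs_df.empty:
                continue
            isel = (ihs_df["chrom"] == reg["chrom"]) & (ihs_df["pos"] >= reg["start"]) & (ihs_df["pos"] < reg["end"])
            hits = ihs_df[isel & ihs_df["outlier"]]
            triggered = (len(hits) and neg) if cfg.dating_signals == "tajima_and_ihs" \
                else bool(len(hits))
            if not triggered:
                continue
            top = hits.iloc[np.argmax(hits["neg_log_p"].to_numpy())]
            try:
                lengths = haplotype_decay_lengths(panel, gmap, str(top["chrom"]),
                                                  int(top["pos"]), 1, group=cfg.wolf_it)
                # recombination-clock MLE; the mutation rates are carried as
                # metadata (the optional mutation term needs mismatch counts)
                est = estimate_tmrca(lengths, method="mle", seed=cfg.seed)
                datings.append({
                    "chrom": str(reg["chrom"]), "start": int(reg["start"]), "end": int(reg["end"]),
                    "focal_pos": int(top["pos"]),
                    "t_gens": float(est.t_hat),
                    "ci_gens": [float(est.ci[0]), float(est.ci[1])],
                    "mutation_rates": list(cfg.mutation_rates),
                    "years": generations_to_years([est.t_hat], cfg.generation_time),
                })
            except ValueError as e:
                logger.info("dating skipped for %s:%s-%s: %s", reg["chrom"], reg["start"], reg["end"], e)

        stage = "write"
        os.makedirs(cfg.out_dir, exist_ok=True)
        validated.to_csv(os.path.join(cfg.out_dir, "historical_regions.tsv"), sep="\t", index=False)
        write_bed(candidates, os.path.join(cfg.out_dir, "candidate_regions.bed"))
        taj.to_csv(os.path.join(cfg.out_dir, "tajima_windows.tsv"), sep="\t", index=False)
        ncd.to_csv(os.path.join(cfg.out_dir, "ncd2_windows.tsv"), sep="\t", index=False)
        if not ihs_df.empty:
            ihs_df.to_csv(os.path.join(cfg.out_dir, "ihs.tsv"), sep="\t", index=False)
        with open(os.path.join(cfg.out_dir, "dating.json"), "w") as fh:
            json.dump(datings, fh, indent=2)
        with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
            json.dump({**_manifest(cfg, "historical"), "dropped_related": dropped}, fh, indent=2)
        return {"candidates": candidates, "validated": validated, "tajima": taj,
                "ncd2": ncd, "ihs": ihs_df, "datings": datings,
                "tracks_it": tracks_it, "tracks_eu": tracks_eu}
    except RuntimeError:
        raise
    except Exception as exc:
        raise RuntimeError(f"run_historical failed at stage '{stage}': {exc}") from exc
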