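"""Synthetic dataset generator with known ground truth.

Emulates the statistical structure of a genotype x treatment study of ABA
response in wildtype vs an RdDM-deficient (mop1-like) mutant:

* four conditions (WT_MS, WT_ABA, MUT_MS, MUT_ABA) and the four pairwise
  differential-expression comparisons between them;
* a configurable fraction of ABA-responsive genes, of which a fraction
  responds only in wildtype (MOP1-dependent) and a fraction responds more
  strongly in the mutant;
* a capture-style methylome over gene promoters: per-cytosine binomial
  counts with context-specific baselines, a genome-wide CHH reduction in the
  mutant (``mutant_chh_scale``) and an ABA-induced CHH gain in wildtype only
  (``wt_aba_chh_gain``), plus an unmethylated chloroplast-like contig whose
  apparent methylation is the bisulfite non-conversion rate;
* promoters with planted ABRE/CE motif instances on an (essentially)
  motif-free random background;
* 24-nt siRNA promoter counts with a global library-composition shift in the
  mutant (``mirna_global_factor``) on top of true depletion at a subset of
  promoters, and miRNA counts that are biologically stable;
* a tiered gene regulatory network seeded with the true primary targets;
* a TE annotation with configurable superfamily weights.

Everything is drawn from one seeded generator, so identical configurations
produce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq
from scipy.stats import norm

from . import core, methylation, motifs
from .core import GeneModel, GenomicInterval, TERecord, TE_SUPERFAMILIES
from .groups import COMPARISONS, bh_adjust

CONDITIONS = ("WT_MS", "WT_ABA", "MUT_MS", "MUT_ABA")

#: concrete ABRE instance matching the consensus CACG[TC]G[TG]C[GC]
ABRE_INSTANCE = "CACGTGTCG"
#: concrete CE instance (the CE3 coupling element)
CE_INSTANCE = "ACGCGTGTCCTC"

CHLOROPLAST = "chrC"


@dataclass
class SimulationConfig:
    """Ground-truth parameters of the synthetic study.

    Defaults reproduce the effects the pipeline is designed to detect: a 68%
    genome-wide CHH reduction in the mutant (scale 0.32), an 11.1% relative
    CHH gain under ABA in wildtype promoters, a 2.2-fold miRNA-anchored
    library-composition factor in the mutant small-RNA libraries, and a
    twofold-change DE effect-size distribution well clear of the 0.95 log2FC
    cutoff.
    """

    seed: int = 0
    # genome & genes
    n_genes: int = 200
    n_chroms: int = 2
    chrom_len: int | None = None  # derived from gene packing when None
    gene_len: int = 1000
    promoter_len: int = 2000
    # expression truth
    frac_aba_responsive: float = 0.4
    frac_mop1_dependent: float = 0.25  # of ABA-responsive: respond in WT only
    frac_amplified_in_mutant: float = 0.3  # of mutant responders
    frac_attenuated_in_mutant: float = 0.3  # of mutant responders: partial response
    frac_rddm_misregulated: float = 0.08  # DE in mutant vs WT without ABA
    effect_lfc_mean: float = 2.0
    effect_lfc_sd: float = 0.8
    min_effect_lfc: float = 1.0  # clip so true effects stay past the cutoff
    amplification: float = 1.8
    de_noise_sd: float = 0.15
    # methylome
    baseline_mc: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.60, "CHG": 0.45, "CHH": 0.02}
    )
    mutant_chh_scale: float = 0.32
    wt_aba_chh_gain: float = 0.111
    read_depth: float = 10.0
    nonconversion_rate: float = 0.005
    chloroplast_len: int = 20000
    # small RNA
    n_sirna_regions: int | None = None  # default: every gene promoter
    frac_sirna_depleted: float = 0.2
    mutant_sirna_scale: float = 0.25
    mirna_global_factor: float = 2.2
    n_mirna: int = 30
    n_sirna_reps: int = 2
    sirna_libsize: int = 2_000_000
    sirna_mean_cpm: float = 20.0
    mirna_mean_cpm: float = 100.0
    # motifs
    abre_plant_rate: float = 0.25  # P(plant two ABREs)
    ce_plant_rate: float = 0.15  # P(plant one ABRE plus one CE)
    # TEs
    n_te: int = 300
    te_superfamily_weights: dict[str, float] | None = None
    # GRN
    grn_n_tiers: int = 3
    grn_out_degree: int = 4
    grn_tissues: tuple[str, ...] = ("leaf", "root", "SAM", "seed")

    def validate(self) -> None:
        fracs = (
            self.frac_aba_responsive, self.frac_mop1_dependent,
            self.frac_amplified_in_mutant, self.frac_attenuated_in_mutant,
            self.frac_rddm_misregulated,
            self.frac_sirna_depleted, self.abre_plant_rate, self.ce_plant_rate,
            self.nonconversion_rate,
        )
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("fractions must be in [0, 1]")
        if self.abre_plant_rate + self.ce_plant_rate > 1:
            raise ValueError("motif planting rates must sum to at most 1")
        positives = (
            self.n_genes, self.n_chroms, self.gene_len, self.promoter_len,
            self.read_depth, self.mutant_chh_scale, self.mirna_global_factor,
            self.mutant_sirna_scale, self.sirna_libsize, self.n_sirna_reps,
        )
        if any(p <= 0 for p in positives):
            raise ValueError("sizes, depths and scales must be positive")
        if any(not 0 < p < 1 for p in self.baseline_mc.values()):
            raise ValueError("baseline methylation levels must be in (0, 1)")
        if self.wt_aba_chh_gain < 0:
            raise ValueError("wt_aba_chh_gain must be non-negative")
        if self.te_superfamily_weights is not None:
            unknown = set(self.te_superfamily_weights) - set(TE_SUPERFAMILIES)
            if unknown:
                raise ValueError(f"unknown TE superfamilies: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grn_tissues"] = list(self.grn_tissues)
        return d


@dataclass
class DatasetBundle:
    """Paths to the generated files plus the in-memory truth table."""

    directory: Path
    files: dict[str, Path]
    truth: pd.DataFrame
    truth_summary: dict

    def path(self, key: str) -> Path:
        return self.files[key]


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length)


def plant_motifs(
    promoter_seq: str,
    n_abre: int,
    n_ce: int,
    rng: np.random.Generator,
    abre_instance: str = ABRE_INSTANCE,
    ce_instance: str = CE_INSTANCE,
) -> tuple[str, list[tuple[str, int]]]:
    """Place motif instances at random non-overlapping promoter positions.

    Returns the modified sequence and ``(motif_name, start)`` records; raises
    when the promoter cannot hold the requested instances without overlap.
    """
    pieces = [("ABRE", abre_instance)] * n_abre + [("CE", ce_instance)] * n_ce
    need = sum(len(s) for _, s in pieces)
    if need > len(promoter_seq):
        raise ValueError("promoter too short for requested motif planting")
    seq = np.frombuffer(promoter_seq.encode(), dtype="S1").copy()
    placed: list[tuple[str, int]] = []
    occupied: list[tuple[int, int]] = []
    for name, instance in pieces:
        m = len(instance)
        for _ in range(200):
            start = int(rng.integers(0, len(seq) - m + 1))
            if all(start + m <= a or start >= b for a, b in occupied):
                break
        else:
            raise ValueError("could not place motifs without overlap")
        occupied.append((start, start + m))
        seq[start : start + m] = np.frombuffer(instance.encode(), dtype="S1")
        placed.append((name, start))
    return seq.tobytes().decode(), placed


def _cytosine_contexts(seq: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Positions, strands and contexts of every cytosine on both strands.

    Positions within two bases of a contig edge are skipped so the trinucleotide
    context is always defined.
    """
    s = seq
    n = len(s)
    is_c = s == b"C"
    is_g = s == b"G"
    pos_list, strand_list, ctx_list = [], [], []
    # plus strand: C at i, context from s[i+1], s[i+2]
    idx = np.flatnonzero(is_c[: n - 2])
    nxt1, nxt2 = s[idx + 1], s[idx + 2]
    ctx = np.where(nxt1 == b"G", "CG", np.where(nxt2 == b"G", "CHG", "CHH"))
    pos_list.append(idx)
    strand_list.append(np.full(len(idx), "+"))
    ctx_list.append(ctx)
    # minus strand: G at i, context from s[i-1], s[i-2] (complemented)
    idx = np.flatnonzero(is_g[2:]) + 2
    prv1, prv2 = s[idx - 1], s[idx - 2]
    ctx = np.where(prv1 == b"C", "CG", np.where(prv2 == b"C", "CHG", "CHH"))
    pos_list.append(idx)
    strand_list.append(np.full(len(idx), "-"))
    ctx_list.append(ctx)
    pos = np.concatenate(pos_list)
    order = np.argsort(pos, kind="stable")
    return (
        pos[order],
        np.concatenate(strand_list)[order],
        np.concatenate(ctx_list)[order],
    )


def simulate_methylome(
    config: SimulationConfig,
    genome: Mapping[str, np.ndarray],
    genes: Sequence[GeneModel],
    rng: np.random.Generator,
) -> dict[str, pd.DataFrame]:
    """Per-condition cytosine call tables over gene promoters plus the
    chloroplast-like contig.

    Methylation probability is the context baseline, times
    ``mutant_chh_scale`` for CHH in the mutant conditions, times
    ``1 + wt_aba_chh_gain`` for CHH in ABA-treated wildtype (the gain is
    promoter-borne; every captured site here is a promoter site). Coverage is
    Poisson around ``read_depth`` and methylated counts are binomial;
    zero-coverage sites are omitted, as in real pileups.
    """
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    site_frames = []
    for chrom, seq in genome.items():
        if chrom == CHLOROPLAST:
            continue
        mask = np.zeros(len(seq), dtype=bool)
        for gene in genes:
            if gene.chrom != chrom:
                continue
            promoter = core.promoter_region(gene, config.promoter_len, chrom_lengths)
            mask[promoter.start : promoter.end] = True
        pos, strand, ctx = _cytosine_contexts(seq)
        keep = mask[pos]
        site_frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos[keep],
                    "strand": strand[keep],
                    "context": ctx[keep],
                }
            )
        )
    if CHLOROPLAST in genome:
        pos, strand, ctx = _cytosine_contexts(genome[CHLOROPLAST])
        site_frames.append(
            pd.DataFrame(
                {"chrom": CHLOROPLAST, "pos": pos, "strand": strand, "context": ctx}
            )
        )
    sites = pd.concat(site_frames, ignore_index=True)

    tables: dict[str, pd.DataFrame] = {}
    base = np.array([config.baseline_mc[c] for c in sites["context"]])
    is_chh = (sites["context"] == "CHH").to_numpy()
    is_plastid = (sites["chrom"] == CHLOROPLAST).to_numpy()
    for condition in CONDITIONS:
        p = base.copy()
        if condition.startswith("MUT"):
            p[is_chh] *= config.mutant_chh_scale
        if condition == "WT_ABA":
            p[is_chh] *= 1.0 + config.wt_aba_chh_gain
        p[is_plastid] = config.nonconversion_rate
        coverage = rng.poisson(config.read_depth, size=len(sites))
        n_meth = rng.binomial(coverage, p)
        covered = coverage > 0
        df = sites.loc[covered].copy()
        df["n_meth"] = n_meth[covered]
        df["n_total"] = coverage[covered]
        tables[condition] = df.reset_index(drop=True)
    return tables


# ---------------------------------------------------------------------------
# the full bundle
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig, outdir: str | Path) -> DatasetBundle:
    """Generate the complete toy dataset and write it under ``outdir``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- genome and gene placement -------------------------------------
    per_chrom = -(-config.n_genes // config.n_chroms)
    slot = config.promoter_len + config.gene_len + 1000
    chrom_len = config.chrom_len or per_chrom * slot + config.promoter_len + 1000
    genome: dict[str, np.ndarray] = {
        f"chr{i + 1}": random_sequence(rng, chrom_len)
        for i in range(config.n_chroms)
    }
    genome[CHLOROPLAST] = random_sequence(rng, config.chloroplast_len)

    genes: list[GeneModel] = []
    for i in range(config.n_genes):
        chrom = f"chr{i % config.n_chroms + 1}"
        j = i // config.n_chroms
        start = config.promoter_len + 500 + j * slot
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"gene{i + 1:05d}",
                chrom=chrom,
                strand=strand,
                start=start,
                end=start + config.gene_len,
            )
        )
    chrom_lengths = {c: len(s) for c, s in genome.items()}

    # --- expression truth ----------------------------------------------
    n = config.n_genes
    responsive = rng.random(n) < config.frac_aba_responsive
    mop1_dep = responsive & (rng.random(n) < config.frac_mop1_dependent)
    amplified = responsive & ~mop1_dep & (
        rng.random(n) < config.frac_amplified_in_mutant
    )
    attenuated = responsive & ~mop1_dep & ~amplified & (
        rng.random(n) < config.frac_attenuated_in_mutant
    )
    misreg = rng.random(n) < config.frac_rddm_misregulated
    sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    effect = np.maximum(
        rng.normal(config.effect_lfc_mean, config.effect_lfc_sd, size=n),
        config.min_effect_lfc,
    )
    mis_effect = np.maximum(
        rng.normal(config.effect_lfc_mean, config.effect_lfc_sd, size=n),
        config.min_effect_lfc,
    ) * np.where(rng.random(n) < 0.5, 1.0, -1.0)

    # additive condition means: WT_MS = 0; WT_ABA = a_wt; MUT_MS = m;
    # MUT_ABA = m + a_mut
    a_wt = np.where(responsive, sign * effect, 0.0)
    # mutant response scale: amplified, attenuated (partial, possibly below
    # the significance cutoff), or matching the wildtype response
    mut_scale = np.where(
        amplified,
        config.amplification,
        np.where(attenuated, rng.uniform(0.3, 0.75, size=n), 1.0),
    )
    a_mut = np.where(responsive & ~mop1_dep, sign * effect * mut_scale, 0.0)
    m = np.where(misreg, mis_effect, 0.0)
    true_lfc = {
        "WTABA_vs_WTMS": a_wt,
        "MUTMS_vs_WTMS": m,
        "MUTABA_vs_MUTMS": a_mut,
        "MUTABA_vs_WTABA": m + a_mut - a_wt,
    }

    gene_ids = [g.gene_id for g in genes]
    files: dict[str, Path] = {}
    for comparison in COMPARISONS:
        true = true_lfc[comparison]
        noise = (
            rng.normal(0.0, config.de_noise_sd, size=n)
            if config.de_noise_sd > 0
            else np.zeros(n)
        )
        obs = true + noise
        if config.de_noise_sd > 0:
            z = np.abs(obs) / config.de_noise_sd
            pvalue = 2.0 * norm.sf(z)
        else:
            pvalue = np.where(true != 0.0, 0.0, 1.0)
        df = pd.DataFrame(
            {"gene_id": gene_ids, "log2fc": obs, "pvalue": pvalue}
        )
        df["fdr"] = bh_adjust(df["pvalue"]).to_numpy()
        path = outdir / f"de_{comparison}.tsv"
        df.to_csv(path, sep="\t", index=False)
        files[f"de_{comparison}"] = path

    # --- motif planting -------------------------------------------------
    u = rng.random(n)
    plant_two_abre = u < config.abre_plant_rate
    plant_abre_ce = (~plant_two_abre) & (
        u < config.abre_plant_rate + config.ce_plant_rate
    )
    planted_abre = np.where(plant_two_abre, 2, np.where(plant_abre_ce, 1, 0))
    planted_ce = np.where(plant_abre_ce, 1, 0)
    for i, gene in enumerate(genes):
        if planted_abre[i] == 0 and planted_ce[i] == 0:
            continue
        region = core.promoter_region(gene, config.promoter_len, chrom_lengths)
        seq = genome[gene.chrom]
        sub = seq[region.start : region.end].tobytes().decode()
        if gene.strand == "-":
            sub = str(Seq(sub).reverse_complement())
        planted_seq, _ = plant_motifs(
            sub, int(planted_abre[i]), int(planted_ce[i]), rng
        )
        if gene.strand == "-":
            planted_seq = str(Seq(planted_seq).reverse_complement())
        seq[region.start : region.end] = np.frombuffer(
            planted_seq.encode(), dtype="S1"
        )

    genome_str = {c: s.tobytes().decode() for c, s in genome.items()}
    files["genome"] = outdir / "genome.fa"
    core.write_genome_fasta(genome_str, files["genome"])
    files["genes"] = outdir / "genes.gff3"
    core.write_gene_models(genes, files["genes"])

    # observed motif counts by re-scanning (background hits are possible but
    # rare on a uniform background: ~2L/4^9 per promoter for the ABRE)
    abre_spec = motifs.abre_motif()
    ce_spec = ce_motif_spec()
    observed_abre = np.zeros(n, dtype=int)
    observed_ce = np.zeros(n, dtype=int)
    for i, gene in enumerate(genes):
        seq = core.promoter_sequence(gene, genome_str, config.promoter_len)
        observed_abre[i] = len(motifs.scan_motif(seq, abre_spec))
        observed_ce[i] = len(motifs.scan_motif(seq, ce_spec))

    deg_mut_aba = np.abs(true_lfc["MUTABA_vs_MUTMS"]) >= 0.95
    primary_truth = deg_mut_aba & (
        (observed_abre >= 2) | ((observed_abre >= 1) & (observed_ce >= 1))
    )

    # --- methylome -------------------------------------------------------
    meth_tables = simulate_methylome(config, genome, genes, rng)
    for condition, table in meth_tables.items():
        path = outdir / f"meth_{condition}.tsv"
        methylation.write_cytosine_calls(table, path)
        files[f"meth_{condition}"] = path

    # --- small RNA -------------------------------------------------------
    n_regions = config.n_sirna_regions or n
    region_genes = gene_ids[:n_regions]
    depleted = rng.random(n_regions) < config.frac_sirna_depleted
    wt_cpm = rng.lognormal(np.log(config.sirna_mean_cpm), 0.5, size=n_regions)
    f = config.mirna_global_factor
    sirna_rows = []
    for rep in range(1, config.n_sirna_reps + 1):
        lam_wt = wt_cpm * config.sirna_libsize / 1e6
        scale = np.where(depleted, config.mutant_sirna_scale, 1.0)
        lam_mut = wt_cpm * scale * f * config.sirna_libsize / 1e6
        c_wt = rng.poisson(lam_wt)
        c_mut = rng.poisson(lam_mut)
        for gid, cw, cm in zip(region_genes, c_wt, c_mut):
            sirna_rows.append((gid, "WT", rep, int(cw)))
            sirna_rows.append((gid, "MUT", rep, int(cm)))
    sirna_df = pd.DataFrame(
        sirna_rows, columns=["gene_id", "genotype", "replicate", "count"]
    )
    files["sirna_counts"] = outdir / "sirna_counts.tsv"
    sirna_df.to_csv(files["sirna_counts"], sep="\t", index=False)

    mirna_cpm = rng.lognormal(np.log(config.mirna_mean_cpm), 0.5, size=config.n_mirna)
    mirna_rows = []
    for rep in range(1, config.n_sirna_reps + 1):
        c_wt = rng.poisson(mirna_cpm * config.sirna_libsize / 1e6)
        c_mut = rng.poisson(mirna_cpm * f * config.sirna_libsize / 1e6)
        for k in range(config.n_mirna):
            mirna_rows.append((f"miR{k + 1:03d}", "WT", rep, int(c_wt[k])))
            mirna_rows.append((f"miR{k + 1:03d}", "MUT", rep, int(c_mut[k])))
    mirna_df = pd.DataFrame(
        mirna_rows, columns=["mirna_id", "genotype", "replicate", "count"]
    )
    files["mirna_counts"] = outdir / "mirna_counts.tsv"
    mirna_df.to_csv(files["mirna_counts"], sep="\t", index=False)

    libsize_rows = [
        (genotype, rep, config.sirna_libsize)
        for genotype in ("WT", "MUT")
        for rep in range(1, config.n_sirna_reps + 1)
    ]
    libsizes = pd.DataFrame(libsize_rows, columns=["genotype", "replicate", "libsize"])
    files["libsizes"] = outdir / "libsizes.tsv"
    libsizes.to_csv(files["libsizes"], sep="\t", index=False)

    # --- transposable elements ------------------------------------------
    weights = config.te_superfamily_weights or {
        code: 1.0 for code in TE_SUPERFAMILIES
    }
    codes = list(weights)
    probs = np.array([weights[c] for c in codes], dtype=float)
    probs /= probs.sum()
    te_records: list[TERecord] = []
    chrom_names = [c for c in genome if c != CHLOROPLAST]
    for k in range(config.n_te):
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        length = int(rng.integers(300, 3000))
        start = int(rng.integers(0, chrom_lengths[chrom] - length))
        te_records.append(
            TERecord(
                te_id=f"TE{k + 1:05d}",
                superfamily=codes[int(rng.choice(len(codes), p=probs))],
                interval=GenomicInterval(chrom, start, start + length),
            )
        )
    files["te"] = outdir / "te.gff3"
    core.write_te_records(te_records, files["te"])

    # --- gene regulatory network -----------------------------------------
    grn_rows = []
    primaries = [g for g, p in zip(gene_ids, primary_truth) if p]
    deg_genes = [
        g for g, d in zip(gene_ids, deg_mut_aba) if d
    ]
    tier_pool = list(primaries)
    others = [g for g in gene_ids if g not in set(primaries)]
    tier_sizes = [max(3, len(primaries) // 2 or 3)] * config.grn_n_tiers
    prev_tier: list[str] = []
    for tier_no, size in enumerate(tier_sizes, start=1):
        take = min(size, len(tier_pool))
        tier = tier_pool[:take]
        tier_pool = tier_pool[take:]
        while len(tier) < size and others:
            tier.append(others.pop(0))
        # edges: every member of this tier regulates out_degree targets,
        # biased toward DEGs so the cascade reaches them
        for reg in tier:
            for _ in range(config.grn_out_degree):
                if deg_genes and rng.random() < 0.7:
                    target = deg_genes[int(rng.integers(0, len(deg_genes)))]
                else:
                    target = gene_ids[int(rng.integers(0, n))]
                if target == reg:
                    continue
                tissue = config.grn_tissues[
                    int(rng.integers(0, len(config.grn_tissues)))
                ]
                grn_rows.append((reg, target, tissue, str(tier_no)))
        prev_tier = tier
    grn_df = pd.DataFrame(grn_rows, columns=["regulator", "target", "tissue", "tier"])
    files["grn"] = outdir / "grn_edges.tsv"
    grn_df.to_csv(files["grn"], sep="\t", index=False)

    # --- truth table & manifest ------------------------------------------
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "aba_responsive": responsive,
            "mop1_dependent": mop1_dep,
            "amplified_in_mutant": amplified,
            "attenuated_in_mutant": attenuated,
            "rddm_misregulated": misreg,
            **{
                f"true_lfc_{c}": np.round(true_lfc[c], 6) for c in COMPARISONS
            },
            "planted_abre": planted_abre,
            "planted_ce": planted_ce,
            "observed_abre": observed_abre,
            "observed_ce": observed_ce,
            "primary_target": primary_truth,
        }
    )
    files["truth_genes"] = outdir / "truth_genes.tsv"
    truth.to_csv(files["truth_genes"], sep="\t", index=False)

    sirna_truth = pd.DataFrame(
        {"gene_id": region_genes, "sirna_depleted": depleted}
    )
    files["truth_sirna"] = outdir / "truth_sirna.tsv"
    sirna_truth.to_csv(files["truth_sirna"], sep="\t", index=False)

    truth_summary = {
        "mutant_chh_scale": config.mutant_chh_scale,
        "wt_aba_chh_gain": config.wt_aba_chh_gain,
        "mirna_global_factor": config.mirna_global_factor,
        "mutant_sirna_scale": config.mutant_sirna_scale,
        "nonconversion_rate": config.nonconversion_rate,
        "n_primary_true": int(primary_truth.sum()),
        "n_sirna_depleted_true": int(depleted.sum()),
    }
    files["truth_summary"] = outdir / "truth_summary.json"
    files["truth_summary"].write_text(
        json.dumps(truth_summary, indent=2, sort_keys=True) + "\n"
    )

    files["config"] = outdir / "config.yaml"
    files["config"].write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))

    manifest = {
        "seed": config.seed,
        "files": {
            key: {
                "name": path.name,
                "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
            }
            for key, path in sorted(files.items())
        },
    }
    files["manifest"] = outdir / "manifest.json"
    files["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return DatasetBundle(
        directory=outdir, files=files, truth=truth, truth_summary=truth_summary
    )


def ce_motif_spec() -> motifs.MotifSpec:
    """Motif spec matching the planted CE instance."""
    return motifs.MotifSpec("CE", CE_INSTANCE)
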