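"""Synthetic multi-omic time course with a ground-truth manifest.

Emulates the assays of a synchronised stem-cell differentiation study at
desk scale: duplicate ATAC insertion tracks at successive time points with
planted protected footprints and 6-mer insertion bias plus a deproteinised
control, histone-mark read sets with scripted enhancer-class transitions,
and a temporally clustered expression matrix with genes optionally coupled
to accessibility changes.

Every planted signal is recorded in a :class:`GroundTruthManifest`;
downstream tests consult only the manifest, never generator internals.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval, IntervalSet
from .sequtils import kmer_ids, kmer_to_id, revcomp, revcomp_id_table

BASES = "ACGT"


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage substream seed below 2**31."""
    return (seed ^ zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic time course.

    Defaults reproduce the study design: 7 time points 0-72 h in 12-h steps,
    duplicate ATAC/ChIP libraries, triplicate RNA, and a desk-scale genome
    (2 x 500 kb) that keeps a full run in minutes.
    """

    seed: int = 0
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 500_000, "chr2": 500_000}
    )
    time_points: Sequence[int] = (0, 12, 24, 36, 48, 60, 72)
    atac_replicates: int = 2
    chip_replicates: int = 2
    rna_replicates: int = 3

    # open chromatin / ATAC
    n_open_regions: int = 200
    region_width: int = 1000
    region_rate: float = 1.0  # expected insertions per bp per strand inside a region
    background_rate: float = 0.0005
    frac_differential: float = 0.3  # regions stepping between consecutive time points
    differential_fold: float = 4.0
    control_rate: float = 0.3  # deproteinised control insertions per bp (both strands)

    # footprints
    n_motif_sites: int = 300
    motif_length: int = 12
    protection_depth: float = 0.8
    occupancy: float = 0.8
    bias: Mapping[str, float] = field(default_factory=dict)  # 6-mer -> multiplier

    # ChIP / enhancers
    n_enhancers: int = 60
    enhancer_width: int = 6000
    chip_read_length: int = 75
    chip_domain_rate: float = 0.05  # reads per bp inside a mark domain
    chip_background_rate: float = 0.0002

    # expression
    n_genes: int = 600
    k_true: int = 3
    expr_noise_sd: float = 0.1
    frac_coupled: float = 0.25
    gene_length: int = 2000
    library_size: int = 20_000_000


@dataclass
class GroundTruthManifest:
    """Planted truth for every simulated signal."""

    regions: pd.DataFrame  # chrom,start,end,region_id + amp_<t> per time point
    motif_sites: pd.DataFrame  # chrom,start,end,strand,pwm + bound_<t>
    enhancers: pd.DataFrame  # chrom,start,end,enh_id + class_<t>,intersection_<t>
    genes: pd.DataFrame  # gene_id,chrom,tss,strand,cluster,coupled,region_id
    expr_log2fc: pd.DataFrame  # gene x transition true log2 fold change
    de_genes: pd.DataFrame  # gene_id,transition,log2fc for truth-differential genes

    def region_fold_changes(self, t1: int, t2: int) -> pd.Series:
        fc = self.regions[f"amp_{t2}"] / self.regions[f"amp_{t1}"]
        fc.index = self.regions.region_id
        return fc


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


def consensus_pwm(consensus: str, name: str = "PWM", soft: float = 0.94) -> dict:
    """PWM concentrated on a consensus sequence (prob ``soft`` at the
    consensus base, remainder spread evenly)."""
    L = len(consensus)
    m = np.full((L, 4), (1 - soft) / 3)
    for i, b in enumerate(consensus):
        m[i, BASES.index(b)] = soft
    return {"name": name, "matrix": m, "consensus": consensus}


def simulate_genome(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Random genome with embedded motif instances and a TSS table.

    Returns (sequences, regions, motif_sites, genes, pwm) where ``regions``
    carries per-time-point amplitudes and ``motif_sites`` per-time-point
    bound labels.
    """
    if not config.chrom_lengths:
        raise ValueError("at least one chromosome required")
    rng = rng or np.random.default_rng(stage_seed(config.seed, "genome"))
    if config.motif_length > min(config.chrom_lengths.values()):
        raise ValueError("motif longer than chromosome")

    seqs = {
        c: "".join(rng.choice(list(BASES), size=n))
        for c, n in config.chrom_lengths.items()
    }

    # open regions: non-overlapping, uniformly placed
    chroms = list(config.chrom_lengths)
    rows = []
    width = config.region_width
    per_chrom = config.n_open_regions // len(chroms) + 1
    rid = 0
    for c in chroms:
        n = config.chrom_lengths[c]
        slots = np.arange(width, n - 2 * width, 2 * width + 200)
        rng.shuffle(slots)
        for s in slots[:per_chrom]:
            if rid >= config.n_open_regions:
                break
            rows.append({"chrom": c, "start": int(s), "end": int(s + width)})
            rid += 1
    # sorted by coordinate so manifest rows align with IntervalSet order
    regions = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    regions.insert(0, "region_id", [f"region_{i}" for i in range(len(regions))])

    # amplitude trajectories: a subset of regions steps up or down by
    # `differential_fold` at one scripted transition; the rest are invariant
    tps = list(config.time_points)
    amps = np.ones((len(regions), len(tps)))
    n_diff = (
        int(round(config.frac_differential * len(regions))) if len(tps) > 1 else 0
    )
    diff_idx = rng.choice(len(regions), size=n_diff, replace=False)
    for i in diff_idx:
        k = rng.integers(1, len(tps))  # transition index: change takes effect at tps[k]
        direction = rng.choice([1.0, -1.0])
        fold = config.differential_fold if direction > 0 else 1.0 / config.differential_fold
        amps[i, k:] *= fold
    for j, t in enumerate(tps):
        regions[f"amp_{t}"] = amps[:, j] * config.region_rate

    # embed motif instances inside open regions
    pwm = consensus_pwm("TGACGTCATGCA"[: config.motif_length], name="SIM1")
    cons = pwm["consensus"]
    site_rows = []
    seq_mut = {c: list(s) for c, s in seqs.items()}
    n_sites = min(config.n_motif_sites, len(regions) * 3)
    host = rng.choice(len(regions), size=n_sites, replace=True)
    used: dict[int, list[tuple[int, int]]] = {}
    for sid, ri in enumerate(host):
        reg = regions.iloc[ri]
        lo, hi = reg.start + 50, reg.end - 50 - len(cons)
        for _ in range(20):
            pos = int(rng.integers(lo, hi))
            if all(abs(pos - p) > len(cons) + 30 for p, _ in used.get(ri, [])):
                break
        else:
            continue
        used.setdefault(ri, []).append((pos, sid))
        strand = "+" if rng.random() < 0.5 else "-"
        planted = cons if strand == "+" else revcomp(cons)
        seq_mut[reg.chrom][pos : pos + len(cons)] = list(planted)
        row = {
            "site_id": f"site_{sid}",
            "chrom": reg.chrom,
            "start": pos,
            "end": pos + len(cons),
            "strand": strand,
            "pwm": pwm["name"],
            "region_id": reg.region_id,
        }
        occupied = rng.random() < config.occupancy
        for t in tps:
            row[f"bound_{t}"] = bool(occupied)
        site_rows.append(row)
    seqs = {c: "".join(v) for c, v in seq_mut.items()}
    motif_sites = pd.DataFrame(site_rows)

    # genes: TSS placed 1 kb downstream of a region so the 10-kb upstream
    # promoter window covers that region; remainder placed at random
    gene_rows = []
    for g in range(config.n_genes):
        if g < len(regions):
            reg = regions.iloc[g]
            tss = int(reg.end + 1000)
            chrom, region_id = reg.chrom, reg.region_id
        else:
            chrom = chroms[g % len(chroms)]
            tss = int(rng.integers(15_000, config.chrom_lengths[chrom] - 15_000))
            region_id = ""
        gene_rows.append(
            {"gene_id": f"gene_{g}", "chrom": chrom, "tss": tss, "strand": "+", "region_id": region_id}
        )
    genes = pd.DataFrame(gene_rows)
    return seqs, regions, motif_sites, genes, pwm


# ---------------------------------------------------------------------------
# ATAC insertions
# ---------------------------------------------------------------------------


def _bias_arrays(seqs: Mapping[str, str], bias: Mapping[str, float]) -> dict:
    """Per-base multiplicative bias for +/- strand insertions.

    The multiplier of the 6-mer spanning [site-3, site+3) applies to a
    forward-strand insertion at ``site``; reverse-strand insertions use the
    reverse complement of that 6-mer.
    """
    k = 6
    mult = np.ones(4**k)
    for kmer, m in bias.items():
        mult[kmer_to_id(kmer)] = m
    rc = revcomp_id_table(k)
    out = {}
    for c, s in seqs.items():
        n = len(s)
        bf = np.ones(n)
        br = np.ones(n)
        if bias:
            ids = kmer_ids(s, k)  # id of k-mer starting at each position
            # the 6-mer [p-3, p+3) starts at p-3
            pos = np.arange(3, n - k + 4)
            valid = ids[pos - 3] >= 0
            bf[pos[valid]] = mult[ids[pos - 3][valid]]
            br[pos[valid]] = mult[rc[ids[pos - 3][valid]]]
        out[c] = (bf, br)
    return out


def _draw_insertions(rate_f: np.ndarray, rate_r: np.ndarray, chrom: str, rng) -> pd.DataFrame:
    rows = []
    for strand, rate in (("+", rate_f), ("-", rate_r)):
        counts = rng.poisson(rate)
        pos = np.repeat(np.arange(len(rate)), counts)
        if len(pos):
            rows.append(pd.DataFrame({"chrom": chrom, "pos": pos, "strand": strand}))
    if not rows:
        return pd.DataFrame(columns=["chrom", "pos", "strand"])
    return pd.concat(rows, ignore_index=True)


def simulate_atac(
    config: SimulationConfig,
    seqs: Mapping[str, str],
    regions: pd.DataFrame,
    motif_sites: pd.DataFrame,
    rng: np.random.Generator | None = None,
):
    """Poisson Tn5 insertion sets per time point and replicate, plus a
    deproteinised control.

    The per-base insertion rate is background + region amplitude, scaled by
    the strand-specific 6-mer bias multiplier, and attenuated by
    (1 - protection_depth) inside occupied motifs. The control sees bias
    only: no open regions and no protection.
    """
    rng = rng or np.random.default_rng(stage_seed(config.seed, "atac"))
    biases = _bias_arrays(seqs, config.bias)
    tps = list(config.time_points)

    base = {c: np.full(len(s), config.background_rate) for c, s in seqs.items()}
    atac: dict[int, list[pd.DataFrame]] = {}
    for t in tps:
        rate = {c: v.copy() for c, v in base.items()}
        for _, reg in regions.iterrows():
            rate[reg.chrom][reg.start : reg.end] += reg[f"amp_{t}"]
        for _, site in motif_sites.iterrows():
            if site[f"bound_{t}"]:
                rate[site.chrom][site.start : site.end] *= 1 - config.protection_depth
        reps = []
        for _ in range(config.atac_replicates):
            parts = [
                _draw_insertions(rate[c] * bf, rate[c] * br, c, rng)
                for c, (bf, br) in biases.items()
            ]
            reps.append(pd.concat(parts, ignore_index=True))
        atac[t] = reps

    control_parts = []
    half = config.control_rate / 2.0
    for c, (bf, br) in biases.items():
        control_parts.append(_draw_insertions(half * bf, half * br, c, rng))
    control = pd.concat(control_parts, ignore_index=True)
    return atac, control


# ---------------------------------------------------------------------------
# ChIP reads and enhancer scripts
# ---------------------------------------------------------------------------

ENHANCER_CLASSES = (
    "poised",
    "active_proximal",
    "active_distal",
    "super_proximal",
    "super_distal",
)


def script_enhancers(config: SimulationConfig, seqs: Mapping[str, str], rng=None) -> pd.DataFrame:
    """Script enhancer anchors with a class per time point.

    Each anchor is an H3K4me1 domain; classes transition over time so that
    poised->active conversions and transient super-enhancers occur.
    """
    rng = rng or np.random.default_rng(stage_seed(config.seed, "enh_script"))
    tps = list(config.time_points)
    chroms = list(seqs)
    rows = []
    pos = {c: 20_000 for c in chroms}
    for e in range(config.n_enhancers):
        c = chroms[e % len(chroms)]
        start = pos[c]
        pos[c] += config.enhancer_width + 8000
        if pos[c] > len(seqs[c]) - config.enhancer_width:
            continue
        start_class = rng.choice(ENHANCER_CLASSES)
        switch = int(rng.integers(1, len(tps)))
        end_class = rng.choice(ENHANCER_CLASSES)
        row = {"enh_id": f"enh_{e}", "chrom": c, "start": start, "end": start + config.enhancer_width}
        for j, t in enumerate(tps):
            row[f"class_{t}"] = start_class if j < switch else end_class
        rows.append(row)
    return pd.DataFrame(rows)


def _mark_domains(enhancers: pd.DataFrame, t: int, se_margin: int = 1000):
    """Realise mark domains for one time point from the enhancer script.

    Active classes get a K27ac domain intersecting the K4me1 anchor by
    2 kb (<= 3 kb); super classes by anchor_width - 2*se_margin (4 kb for
    the default 6-kb anchors, strictly > 3 kb); proximal classes
    additionally get a K4me3 domain at the anchor.
    """
    k4me1, k27ac, k4me3 = [], [], []
    for _, r in enhancers.iterrows():
        cls = r[f"class_{t}"]
        anchor = GenomicInterval(r.chrom, r.start, r.end)
        k4me1.append(anchor)
        if cls.startswith("active"):
            k27ac.append(GenomicInterval(r.chrom, r.start + 500, r.start + 2500))
        elif cls.startswith("super"):
            k27ac.append(GenomicInterval(r.chrom, r.start + se_margin, r.end - se_margin))
        if cls.endswith("proximal"):
            k4me3.append(GenomicInterval(r.chrom, r.start, r.start + 1000))
    return IntervalSet(k4me1), IntervalSet(k27ac), IntervalSet(k4me3)


def simulate_chip(
    config: SimulationConfig,
    seqs: Mapping[str, str],
    enhancers: pd.DataFrame,
    rng: np.random.Generator | None = None,
):
    """Read sets per mark and time point over the scripted domains.

    Reads are ``chip_read_length`` bp, drawn per-bp Poisson at
    ``chip_domain_rate`` inside domains plus uniform background. Returns
    (reads, domains) where ``domains[(mark, t)]`` is the true IntervalSet.
    """
    rng = rng or np.random.default_rng(stage_seed(config.seed, "chip"))
    tps = list(config.time_points)
    reads: dict[tuple[str, int], pd.DataFrame] = {}
    domains: dict[tuple[str, int], IntervalSet] = {}
    rl = config.chip_read_length
    for t in tps:
        k4me1, k27ac, k4me3 = _mark_domains(enhancers, t)
        for mark, ivset in (("H3K4me1", k4me1), ("H3K27ac", k27ac), ("H3K4me3", k4me3)):
            domains[(mark, t)] = ivset
            parts = []
            for c, s in seqs.items():
                rate = np.full(len(s) - rl, config.chip_background_rate)
                for iv in ivset:
                    if iv.chrom == c:
                        rate[iv.start : max(iv.start, min(iv.end - rl, len(rate)))] = config.chip_domain_rate
                counts = rng.poisson(rate)
                starts = np.repeat(np.arange(len(rate)), counts)
                if len(starts):
                    strands = np.where(rng.random(len(starts)) < 0.5, "+", "-")
                    parts.append(
                        pd.DataFrame(
                            {"chrom": c, "start": starts, "end": starts + rl, "strand": strands, "mapq": 30}
                        )
                    )
            reads[(mark, t)] = (
                pd.concat(parts, ignore_index=True)
                if parts
                else pd.DataFrame(columns=["chrom", "start", "end", "strand", "mapq"])
            )
    return reads, domains


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def simulate_expression(
    config: SimulationConfig,
    genes: pd.DataFrame,
    regions: pd.DataFrame,
    rng: np.random.Generator | None = None,
):
    """FPKM and count matrices with K_true temporal clusters.

    Gene profiles are cluster means plus Gaussian noise on the log2 scale.
    Genes flagged as accessibility-coupled take their expression log2 fold
    changes from their host region's amplitude trajectory instead of the
    cluster mean. Returns (fpkm, counts, truth) where truth carries cluster
    labels, coupling flags, per-transition log2 fold changes and DE labels
    (>= 1.5-fold on truth means).
    """
    if config.k_true < 1:
        raise ValueError("k_true must be >= 1")
    rng = rng or np.random.default_rng(stage_seed(config.seed, "expr"))
    tps = list(config.time_points)
    T = len(tps)
    K = config.k_true

    # well-separated smooth cluster mean profiles on the log2 scale
    grid = np.linspace(0, 1, T)
    means = np.stack(
        [3.0 + 2.5 * np.sin(np.pi * grid * (k + 1) / 2 + k) + 1.5 * k for k in range(K)]
    )

    n = len(genes)
    cluster = rng.integers(0, K, size=n)
    amp_cols = [f"amp_{t}" for t in tps]
    region_amp = regions.set_index("region_id")[amp_cols]

    coupled = np.zeros(n, dtype=bool)
    eligible = genes.region_id != ""
    n_coupled = int(round(config.frac_coupled * n))
    idx = np.flatnonzero(eligible.to_numpy())[:n_coupled]
    coupled[idx] = True

    log2fpkm = means[cluster] + rng.normal(0, config.expr_noise_sd, size=(n, T))
    for i in np.flatnonzero(coupled):
        amps = region_amp.loc[genes.region_id.iloc[i]].to_numpy()
        profile = 3.0 + np.log2(amps / amps[0])
        log2fpkm[i] = profile + rng.normal(0, config.expr_noise_sd, size=T)

    cols = [f"t{t}" for t in tps]
    fpkm = pd.DataFrame(2.0**log2fpkm, index=genes.gene_id, columns=cols)

    counts = (fpkm * config.library_size * config.gene_length / 1e9).round().astype(int)

    # truth log2 FC per consecutive transition from noiseless means
    truth_log2 = np.empty((n, T))
    for i in range(n):
        if coupled[i]:
            amps = region_amp.loc[genes.region_id.iloc[i]].to_numpy()
            truth_log2[i] = 3.0 + np.log2(amps / amps[0])
        else:
            truth_log2[i] = means[cluster[i]]
    trans_cols = [f"{tps[j]}h_vs_{tps[j+1]}h" for j in range(T - 1)]
    expr_log2fc = pd.DataFrame(
        truth_log2[:, 1:] - truth_log2[:, :-1], index=genes.gene_id, columns=trans_cols
    )

    de_rows = []
    for j, tc in enumerate(trans_cols):
        lfc = expr_log2fc[tc]
        hits = lfc[np.abs(lfc) >= np.log2(1.5)]
        for g, v in hits.items():
            de_rows.append({"gene_id": g, "transition": tc, "log2fc": float(v)})
    de_genes = pd.DataFrame(de_rows, columns=["gene_id", "transition", "log2fc"])

    truth = pd.DataFrame(
        {"gene_id": genes.gene_id, "cluster": cluster, "coupled": coupled}
    )
    return fpkm, counts, truth, expr_log2fc, de_genes


# ---------------------------------------------------------------------------
# Full simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    sequences: dict
    pwm: dict
    atac: dict  # time -> list of insertion DataFrames
    control: pd.DataFrame
    chip_reads: dict  # (mark, time) -> read DataFrame
    chip_domains: dict  # (mark, time) -> IntervalSet
    fpkm: pd.DataFrame
    counts: pd.DataFrame
    truth: GroundTruthManifest


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Run the full generator and assemble the ground-truth manifest."""
    seqs, regions, motif_sites, genes, pwm = simulate_genome(config)
    atac, control = simulate_atac(config, seqs, regions, motif_sites)
    enh = script_enhancers(config, seqs)
    chip_reads, chip_domains = simulate_chip(config, seqs, enh)
    fpkm, counts, gene_truth, expr_log2fc, de_genes = simulate_expression(config, genes, regions)

    tps = list(config.time_points)
    inter_cols = {}
    for t in tps:
        k4me1, k27ac, _ = _mark_domains(enh, t)
        lengths = []
        for _, r in enh.iterrows():
            anchor = IntervalSet([GenomicInterval(r.chrom, r.start, r.end)])
            from .core import intersect_bp

            lengths.append(intersect_bp(anchor, k27ac))
        inter_cols[f"intersection_{t}"] = lengths
    enh = enh.assign(**inter_cols)

    genes_full = genes.merge(gene_truth, on="gene_id")
    truth = GroundTruthManifest(
        regions=regions,
        motif_sites=motif_sites,
        enhancers=enh,
        genes=genes_full,
        expr_log2fc=expr_log2fc,
        de_genes=de_genes,
    )
    return SimulatedStudy(
        config=config,
        sequences=seqs,
        pwm=pwm,
        atac=atac,
        control=control,
        chip_reads=chip_reads,
        chip_domains=chip_domains,
        fpkm=fpkm,
        counts=counts,
        truth=truth,
    )


def write_study(study: SimulatedStudy, outdir) -> None:
    """Write the simulated study as plain-text files plus a manifest."""
    import json
    import os

    from .core import write_fasta

    os.makedirs(outdir, exist_ok=True)
    write_fasta(study.sequences, os.path.join(outdir, "genome.fa"))
    np.savetxt(
        os.path.join(outdir, f"pwm_{study.pwm['name']}.tsv"),
        study.pwm["matrix"],
        delimiter="\t",
        header="A\tC\tG\tT",
        comments="",
    )
    for t, reps in study.atac.items():
        for r, df in enumerate(reps):
            df.to_csv(os.path.join(outdir, f"atac_t{t}_rep{r+1}.tsv"), sep="\t", index=False)
    study.control.to_csv(os.path.join(outdir, "atac_deproteinised.tsv"), sep="\t", index=False)
    for (mark, t), df in study.chip_reads.items():
        df.to_csv(os.path.join(outdir, f"chip_{mark}_t{t}.tsv"), sep="\t", index=False)
    study.fpkm.to_csv(os.path.join(outdir, "expression_fpkm.tsv"), sep="\t")
    study.counts.to_csv(os.path.join(outdir, "expression_counts.tsv"), sep="\t")
    tr = study.truth
    tr.regions.to_csv(os.path.join(outdir, "truth_regions.tsv"), sep="\t", index=False)
    tr.motif_sites.to_csv(os.path.join(outdir, "truth_motif_sites.tsv"), sep="\t", index=False)
    tr.enhancers.to_csv(os.path.join(outdir, "truth_enhancers.tsv"), sep="\t", index=False)
    tr.genes.to_csv(os.path.join(outdir, "truth_genes.tsv"), sep="\t", index=False)
    tr.expr_log2fc.to_csv(os.path.join(outdir, "truth_expr_log2fc.tsv"), sep="\t")
    tr.de_genes.to_csv(os.path.join(outdir, "truth_de_genes.tsv"), sep="\t", index=False)
    manifest = {
        "seed": study.config.seed,
        "time_points": list(study.config.time_points),
        "chromosomes": {c: len(s) for c, s in study.sequences.items()},
        "files": sorted(os.listdir(outdir)),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
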