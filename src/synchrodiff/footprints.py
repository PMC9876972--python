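"""Digital genomic footprinting from Tn5 insertion profiles.

Candidate motif matches come from a log-odds PWM scan with exact p-values.
Insertion counts in a window of motif +/- 25 bp are explained by a
two-component multinomial mixture: an unbound component proportional to the
sequence-bias weights (learned from a deproteinised control) and a bound
component additionally attenuated by a shared protection shape over the
motif. The footprint likelihood ratio (FLR) is the natural-log likelihood
ratio of the two components at the converged fit; matches with FLR >= 10 in
every replicate are 'bound' and then pass through a consensus curation
chain (reproducibility, per-PWM support, protection score, single-TF PWM,
expression, redundancy removal, optional external evidence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomicInterval, IntervalSet
from .sequtils import id_to_kmer, kmer_ids, kmer_to_id, revcomp_id_table

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class PWM:
    """Position probability matrix (L x 4, columns A,C,G,T)."""

    name: str
    matrix: np.ndarray
    tfs: tuple[str, ...] = ()

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM columns must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]


def read_pwm_tsv(path, name: str | None = None) -> PWM:
    """Read a plain 4-column (A,C,G,T) probability matrix TSV."""
    df = pd.read_csv(path, sep="\t")
    cols = [c for c in df.columns if c.upper() in BASES]
    m = df[cols].to_numpy() if len(cols) == 4 else df.to_numpy()
    return PWM(name or str(path), m)


def read_meme_motifs(path) -> list[PWM]:
    """Read motifs from MEME minimal format."""
    pwms = []
    name, rows = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                if name and rows:
                    pwms.append(PWM(name, np.array(rows)))
                name, rows = line.split()[1], []
            elif name and line and line[0].isdigit() or (name and line.startswith("0.")):
                rows.append([float(x) for x in line.split()])
    if name and rows:
        pwms.append(PWM(name, np.array(rows)))
    return pwms


# ---------------------------------------------------------------------------
# PWM scanning with exact score-distribution p-values
# ---------------------------------------------------------------------------


def _score_threshold(logodds_int: np.ndarray, background: np.ndarray, p_threshold: float) -> int:
    """Smallest integer score with P(score >= s | background) < p_threshold.

    Exact distribution by dynamic programming over the integer score
    histogram (per-column convolution).
    """
    offset = -logodds_int.min(axis=1)
    shifted = (logodds_int + offset[:, None]).astype(int)
    dist = np.array([1.0])
    for i in range(shifted.shape[0]):
        width = shifted[i].max() + 1
        new = np.zeros(len(dist) + width - 1)
        for b in range(4):
            s = shifted[i, b]
            new[s : s + len(dist)] += background[b] * dist
        dist = new
    tail = np.concatenate([np.cumsum(dist[::-1])[::-1], [0.0]])
    # smallest shifted score s with tail[s] < p
    s = int(np.searchsorted(-tail, -p_threshold, side="right"))
    while s < len(tail) - 1 and tail[s] >= p_threshold:
        s += 1
    return s - int(offset.sum())


def scan_pwm(
    genome: dict[str, str],
    pwm: PWM,
    p_threshold: float = 1e-4,
    background: np.ndarray | None = None,
    pseudocount: float = 1e-3,
    precision: int = 1000,
) -> pd.DataFrame:
    """Scan both strands for matches below the p-value threshold.

    Log-odds scores against a 0-order background; the match p-value is the
    exact tail probability of the integer-discretised score distribution
    under that background.
    """
    if p_threshold <= 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "strand", "score", "pwm"])
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    probs = pwm.matrix + pseudocount
    probs /= probs.sum(axis=1, keepdims=True)
    logodds = np.log2(probs / bg)
    lo_int = np.rint(logodds * precision).astype(int)
    thr = _score_threshold(lo_int, bg, p_threshold)

    L = len(pwm)
    rows = []
    for chrom, seq in genome.items():
        codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        idx = np.full(len(codes), -1, dtype=np.int8)
        for b, i in BASE_INDEX.items():
            idx[codes == ord(b)] = i
        valid = idx >= 0
        n = len(seq) - L + 1
        if n <= 0:
            continue
        for strand in "+-":
            mat = lo_int if strand == "+" else lo_int[::-1, [3, 2, 1, 0]]
            total = np.zeros(n, dtype=np.int64)
            ok = np.ones(n, dtype=bool)
            for off in range(L):
                col = idx[off : off + n]
                ok &= valid[off : off + n]
                total += mat[off][np.clip(col, 0, 3)]
            hits = np.flatnonzero(ok & (total >= thr))
            for h in hits:
                rows.append(
                    {
                        "chrom": chrom,
                        "start": int(h),
                        "end": int(h + L),
                        "strand": strand,
                        "score": total[h] / precision,
                        "pwm": pwm.name,
                    }
                )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "score", "pwm"])
    return df.sort_values(["chrom", "start", "strand"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Tn5 sequence-bias model
# ---------------------------------------------------------------------------


@dataclass
class BiasModel:
    """6-mer insertion-bias weights: control frequency over background
    frequency, both pseudocounted.

    ``weight_array`` is indexed by k-mer ID (base-4 encoding, A=0..T=3).
    """

    weight_array: np.ndarray
    k: int = 6
    pseudocount: float = 1.0

    def weight(self, kmer: str) -> float:
        return float(self.weight_array[kmer_to_id(kmer)])

    @property
    def weights(self) -> dict[str, float]:
        return {id_to_kmer(i, self.k): float(w) for i, w in enumerate(self.weight_array)}

    def position_weights(self, seq: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-base bias weight for forward- and reverse-strand insertions.

        The 6-mer spanning [p-3, p+3) applies to a forward insertion at p;
        the reverse complement applies to a reverse insertion. Positions
        whose 6-mer runs off the sequence or contains N get weight 1.
        """
        n = len(seq)
        wf = np.ones(n)
        wr = np.ones(n)
        half = self.k // 2
        ids = kmer_ids(seq, self.k)
        if len(ids):
            rc = revcomp_id_table(self.k)
            pos = np.arange(half, half + len(ids))
            pos = pos[pos < n]
            kid = ids[pos - half]
            ok = kid >= 0
            wf[pos[ok]] = self.weight_array[kid[ok]]
            wr[pos[ok]] = self.weight_array[rc[kid[ok]]]
        return wf, wr


def genome_kmer_frequencies(genome: dict[str, str], k: int = 6, pseudocount: float = 1.0) -> np.ndarray:
    """k-mer background frequencies from both strands of the genome.

    Equivalent to the stationary k-mer distribution of an order-(k-1)
    Markov model fitted on the sequence; indexed by k-mer ID.
    """
    counts = np.zeros(4**k)
    for seq in genome.values():
        ids = kmer_ids(seq, k)
        ids = ids[ids >= 0]
        counts += np.bincount(ids, minlength=4**k)
    rc = revcomp_id_table(k)
    counts = counts + counts[rc]  # both strands
    counts += pseudocount
    return counts / counts.sum()


def build_bias_model(
    insertions: pd.DataFrame,
    genome: dict[str, str],
    k: int = 6,
    pseudocount: float = 1.0,
    min_insertions: int = 10_000,
) -> BiasModel:
    """Fit the 6-mer bias model from a deproteinised control.

    For each insertion the k-mer covering [site-3, site+3) on the insertion
    strand is counted (reverse-complemented for '-' insertions); the weight
    is the pseudocounted control frequency divided by the genome background
    frequency.
    """
    if len(insertions) < min_insertions:
        warnings.warn(
            f"only {len(insertions)} control insertions; bias weights will be noisy",
            stacklevel=2,
        )
    half = k // 2
    rc = revcomp_id_table(k)
    counts = np.zeros(4**k)
    n_used = 0
    for chrom, grp in insertions.groupby("chrom", sort=False):
        if chrom not in genome:
            raise KeyError(f"insertion chromosome {chrom!r} absent from genome")
        ids = kmer_ids(genome[chrom], k)
        pos = grp.pos.to_numpy()
        neg = grp.strand.to_numpy() == "-"
        ok = (pos - half >= 0) & (pos - half < len(ids))
        pos, neg = pos[ok], neg[ok]
        kid = ids[pos - half]
        valid = kid >= 0
        kid, neg = kid[valid], neg[valid]
        kid = np.where(neg, rc[kid], kid)
        counts += np.bincount(kid, minlength=4**k)
        n_used += len(kid)
    background = genome_kmer_frequencies(genome, k, pseudocount)
    total = n_used + pseudocount * 4**k
    freq = (counts + pseudocount) / total
    return BiasModel(weight_array=freq / background, k=k, pseudocount=pseudocount)


def flat_bias_model(k: int = 6) -> BiasModel:
    """All-ones bias (no correction); the paired control for bias tests."""
    return BiasModel(weight_array=np.ones(4**k), k=k)


# ---------------------------------------------------------------------------
# Two-component mixture footprint model
# ---------------------------------------------------------------------------


def window_counts(
    matches: pd.DataFrame,
    insertions: pd.DataFrame,
    genome: dict[str, str],
    bias: BiasModel,
    flank: int = 25,
) -> tuple[np.ndarray, np.ndarray]:
    """Insertion counts and bias weights per window position for each match.

    Windows are motif +/- flank; '-'-strand matches are reversed so the
    motif orientation is aligned. Both insertion strands are pooled per
    position; the per-position bias weight is the sum of the two strand
    weights.
    """
    ins_by_chrom = {
        c: np.sort(grp.pos.to_numpy()) for c, grp in insertions.groupby("chrom")
    }
    counts = []
    weights = []
    for _, m in matches.iterrows():
        lo, hi = m.start - flank, m.end + flank
        seq = genome[m.chrom]
        w = hi - lo
        c = np.zeros(w)
        pos = ins_by_chrom.get(m.chrom, np.array([], dtype=int))
        sel = pos[(pos >= lo) & (pos < hi)]
        np.add.at(c, sel - lo, 1.0)
        lo_c, hi_c = max(lo, 0), min(hi, len(seq))
        wf, wr = bias.position_weights(seq[lo_c:hi_c])
        bw = np.ones(w)
        bw[lo_c - lo : hi_c - lo] = wf + wr
        if m.strand == "-":
            c = c[::-1]
            bw = bw[::-1]
        counts.append(c)
        weights.append(bw)
    return np.asarray(counts), np.asarray(weights)


@dataclass
class MixtureFit:
    flr: np.ndarray
    protection: np.ndarray  # shared shape over motif positions, in (0, 1]
    weight: float  # mixture weight of the bound component
    converged: bool
    n_iter: int


def fit_footprint_mixture(
    counts: np.ndarray,
    bias_weights: np.ndarray,
    motif_slice: slice,
    max_iter: int = 200,
    tol: float = 1e-6,
    min_matches: int = 100,
) -> MixtureFit:
    """EM fit of the two-component multinomial mixture; FLR per match.

    Unbound profile is proportional to the bias weights; the bound profile
    multiplies the motif positions by a shared protection shape pi in
    (0, 1]. Returns the natural-log likelihood ratio bound/unbound for each
    window at the converged parameters; zero-count windows get FLR 0.
    """
    n, W = counts.shape
    if n < min_matches:
        warnings.warn(f"only {n} matches; below configured minimum {min_matches}", stacklevel=2)
    b = np.maximum(bias_weights, 1e-12)
    q0 = b / b.sum(axis=1, keepdims=True)

    motif_idx = np.arange(W)[motif_slice]
    pi = np.ones(W)
    pi[motif_idx] = 0.5
    w = 0.3

    def bound_profile(pi_vec):
        q = b * pi_vec
        return q / q.sum(axis=1, keepdims=True)

    def loglik_rows(q):
        return counts @ np.log(np.maximum(q, 1e-300)).T if q.ndim == 1 else np.einsum(
            "ij,ij->i", counts, np.log(np.maximum(q, 1e-300))
        )

    ll0 = np.einsum("ij,ij->i", counts, np.log(np.maximum(q0, 1e-300)))
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        q1 = bound_profile(pi)
        ll1 = np.einsum("ij,ij->i", counts, np.log(np.maximum(q1, 1e-300)))
        # E-step
        a = np.log(max(w, 1e-12)) + ll1
        u = np.log(max(1 - w, 1e-12)) + ll0
        mx = np.maximum(a, u)
        r = np.exp(a - mx) / (np.exp(a - mx) + np.exp(u - mx))
        total = np.logaddexp(a, u).sum()
        # M-step: mixture weight and protection shape (MM update for the
        # normalised-multinomial constraint)
        w = float(np.clip(r.mean(), 1e-6, 1 - 1e-6))
        C = (r[:, None] * counts).sum(axis=0)
        Ctot = C.sum()
        if Ctot > 0:
            for _ in range(50):
                q = b * pi
                Z = q.sum(axis=1)  # per-window normaliser; use expected value
                # effective per-position rate aggregated over windows
                denom = ((r * counts.sum(axis=1))[:, None] * (b / Z[:, None])).sum(axis=0)
                new_pi = pi.copy()
                upd = C[motif_idx] / np.maximum(denom[motif_idx], 1e-300)
                new_pi[motif_idx] = np.clip(upd, 1e-4, 1.0)
                if np.max(np.abs(new_pi - pi)) < 1e-8:
                    pi = new_pi
                    break
                pi = new_pi
        if abs(total - prev) < tol * (1 + abs(prev)):
            converged = True
            break
        prev = total
    if not converged:
        warnings.warn("footprint mixture EM did not converge", stacklevel=2)
    q1 = bound_profile(pi)
    ll1 = np.einsum("ij,ij->i", counts, np.log(np.maximum(q1, 1e-300)))
    flr = ll1 - ll0
    flr[counts.sum(axis=1) == 0] = 0.0
    return MixtureFit(flr=flr, protection=pi[motif_idx], weight=w, converged=converged, n_iter=it)


def footprint_flr(
    matches: pd.DataFrame,
    insertions: pd.DataFrame,
    genome: dict[str, str],
    bias: BiasModel,
    flank: int = 25,
    min_matches: int = 100,
) -> pd.DataFrame:
    """Convenience wrapper: window extraction + mixture fit -> FLR column."""
    if matches.empty:
        return matches.assign(flr=pd.Series(dtype=float))
    counts, weights = window_counts(matches, insertions, genome, bias, flank)
    L = int((matches.end - matches.start).iloc[0])
    fit = fit_footprint_mixture(
        counts, weights, slice(flank, flank + L), min_matches=min_matches
    )
    return matches.assign(flr=fit.flr)


def protection_score(
    matches: pd.DataFrame,
    insertions: pd.DataFrame,
    flank: int = 25,
) -> np.ndarray:
    """Protection score: flank mean minus motif mean normalised insertion
    rate, per match.

    Rates are per-base insertion counts scaled per million library
    insertions; positive PS indicates central protection (intermediate/long
    TF residency)."""
    library = max(len(insertions), 1)
    scale = 1e6 / library
    ins_by_chrom = {c: np.sort(g.pos.to_numpy()) for c, g in insertions.groupby("chrom")}
    ps = np.empty(len(matches))
    for i, (_, m) in enumerate(matches.iterrows()):
        pos = ins_by_chrom.get(m.chrom, np.array([], dtype=int))
        lo, hi = m.start - flank, m.end + flank
        sel = pos[(pos >= lo) & (pos < hi)]
        prof = np.zeros(hi - lo)
        np.add.at(prof, sel - lo, scale)
        L = m.end - m.start
        motif = prof[flank : flank + L]
        flanks = np.concatenate([prof[:flank], prof[flank + L :]])
        ps[i] = flanks.mean() - motif.mean()
    return ps


# ---------------------------------------------------------------------------
# Consensus curation
# ---------------------------------------------------------------------------


@dataclass
class CurationConfig:
    flr_min: float = 10.0
    min_footprints_per_pwm: int = 50
    ps_min: float = 0.0
    expression_min: float = 1.0  # FPKM
    require_single_tf: bool = True


def curate_footprints(
    replicate_calls: list[pd.DataFrame],
    pwm_tfs: dict[str, tuple[str, ...]],
    expression: dict[str, float],
    external_set: IntervalSet | None = None,
    config: CurationConfig | None = None,
) -> pd.DataFrame:
    """Apply the consensus curation chain to per-replicate footprint calls.

    Order of the filters: (1) FLR >= threshold in every replicate, mean FLR
    reported; (2) PWMs with fewer surviving footprints than the per-PWM
    floor dropped; (3) negative protection score dropped; (4) PWMs mapping
    to more than one TF dropped; (5) TF genes below the expression floor
    dropped (missing expression drops the TF with a warning); (6) among
    overlapping same-TF calls only the highest mean FLR is kept (ties by
    coordinate); (7) calls must overlap the external evidence set by
    >= 1 bp when one is given.
    """
    cfg = config or CurationConfig()
    key_cols = ["chrom", "start", "end", "strand", "pwm"]
    base = replicate_calls[0][key_cols + ["ps"]].copy() if "ps" in replicate_calls[0] else replicate_calls[0][key_cols].copy()
    flrs = np.stack([df.flr.to_numpy() for df in replicate_calls])
    for df in replicate_calls[1:]:
        if len(df) != len(base):
            raise ValueError("replicate call sets must share the match universe")
    base["flr_mean"] = flrs.mean(axis=0)

    empty_cols = list(base.columns) + ["tf", "curated"]

    # 1. bound in every replicate
    keep = (flrs >= cfg.flr_min).all(axis=0)
    cur = base[keep].copy()
    if cur.empty:
        return pd.DataFrame(columns=empty_cols)

    # 2. per-PWM support floor
    support = cur.groupby("pwm")["pwm"].transform("size")
    cur = cur[support >= cfg.min_footprints_per_pwm]
    if cur.empty:
        return pd.DataFrame(columns=empty_cols)

    # 3. protection score
    if "ps" in cur.columns:
        cur = cur[cur.ps >= cfg.ps_min]

    # 4. single-TF PWMs only
    if cfg.require_single_tf:
        cur = cur[cur.pwm.map(lambda p: len(pwm_tfs.get(p, ())) == 1)]
    cur = cur.assign(tf=cur.pwm.map(lambda p: pwm_tfs.get(p, ("",))[0]))

    # 5. expressed TFs only
    def expressed(tf: str) -> bool:
        if tf not in expression:
            warnings.warn(f"no expression for TF {tf}; dropped", stacklevel=2)
            return False
        return expression[tf] >= cfg.expression_min

    cur = cur[cur.tf.map(expressed)]

    # 6. non-redundant: among overlapping same-TF calls keep highest mean FLR
    cur = cur.sort_values(["tf", "chrom", "start", "end"]).reset_index(drop=True)
    drop = np.zeros(len(cur), dtype=bool)
    for _, grp in cur.groupby(["tf", "chrom"]):
        idx = grp.index.to_numpy()
        i = 0
        while i < len(idx):
            j = i
            cluster = [idx[i]]
            end = cur.end.iloc[idx[i]]
            while j + 1 < len(idx) and cur.start.iloc[idx[j + 1]] < end:
                j += 1
                cluster.append(idx[j])
                end = max(end, cur.end.iloc[idx[j]])
            if len(cluster) > 1:
                best = max(cluster, key=lambda k: (cur.flr_mean.iloc[k], -cur.start.iloc[k]))
                for k in cluster:
                    if k != best:
                        drop[k] = True
            i = j + 1
    cur = cur[~drop]

    # 7. external evidence overlap
    if external_set is not None:
        ivset = IntervalSet(
            GenomicInterval(r.chrom, r.start, r.end) for _, r in cur.iterrows()
        )
        kept = {(iv.chrom, iv.start, iv.end) for iv in ivset.overlapping(external_set)}
        cur = cur[[(r.chrom, r.start, r.end) in kept for _, r in cur.iterrows()]]

    return cur.assign(curated=True).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Differential footprinting statistics
# ---------------------------------------------------------------------------


def footprint_overrepresentation(
    differential: dict[str, int], background: dict[str, int], alpha: float = 0.01
) -> pd.DataFrame:
    """Per-TF 2x2 chi-squared overrepresentation of differential footprints.

    Each TF's count in the differential list vs the rest is compared with
    its count in the background (total) list vs the rest; BH correction
    across TFs."""
    n_diff = sum(differential.values())
    n_bg = sum(background.values())
    if n_diff == 0 or n_bg == 0:
        raise ValueError("totals must be positive")
    rows = []
    for tf, d in differential.items():
        if tf not in background:
            warnings.warn(f"TF {tf} absent from background; skipped", stacklevel=2)
            continue
        b = background[tf]
        table = np.array([[d, n_diff - d], [b, n_bg - b]])
        if table.min() < 0 or table.sum(axis=1).min() == 0:
            continue
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        rows.append({"tf": tf, "diff": d, "background": b, "chi2": chi2, "p": p})
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(p_adj=pd.Series(dtype=float), significant=pd.Series(dtype=bool))
    df["p_adj"] = bh_adjust(df.p.to_numpy())
    df["significant"] = df.p_adj <= alpha
    return df.sort_values("p_adj").reset_index(drop=True)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def bagfoot_metrics(
    matches: pd.DataFrame,
    insertions_c1: pd.DataFrame,
    insertions_c2: pd.DataFrame,
    flank_bp: int = 100,
) -> dict:
    """Bivariate footprint metrics aggregated over one PWM's matches.

    FA (flanking accessibility) is log2 of the depth-normalised mean
    insertion rate over [motif edge + 1, motif edge + flank_bp] on both
    sides; FPD (footprint depth) is (flank mean - motif mean)/flank mean.
    Delta values are condition2 - condition1; significance from a 2x2
    chi-squared on the aggregated raw flank/motif counts.
    """

    def aggregate(ins: pd.DataFrame) -> tuple[float, float, int, int]:
        by_chrom = {c: np.sort(g.pos.to_numpy()) for c, g in ins.groupby("chrom")}
        flank_count = motif_count = 0
        flank_bases = motif_bases = 0
        for _, m in matches.iterrows():
            pos = by_chrom.get(m.chrom, np.array([], dtype=int))
            left = pos[(pos >= m.start - flank_bp) & (pos < m.start)]
            right = pos[(pos >= m.end) & (pos < m.end + flank_bp)]
            inside = pos[(pos >= m.start) & (pos < m.end)]
            flank_count += len(left) + len(right)
            motif_count += len(inside)
            flank_bases += 2 * flank_bp
            motif_bases += m.end - m.start
        scale = 1e6 / max(len(ins), 1)
        flank_rate = flank_count / max(flank_bases, 1) * scale
        motif_rate = motif_count / max(motif_bases, 1) * scale
        return flank_rate, motif_rate, flank_count, motif_count

    f1, m1, fc1, mc1 = aggregate(insertions_c1)
    f2, m2, fc2, mc2 = aggregate(insertions_c2)
    if f1 == 0 or f2 == 0:
        raise ValueError("zero flank counts; PWM should be skipped")
    fa1, fa2 = np.log2(f1), np.log2(f2)
    fpd1 = (f1 - m1) / f1
    fpd2 = (f2 - m2) / f2
    table = np.array([[fc1, mc1], [fc2, mc2]])
    if table.min() > 0:
        _, p, _, _ = stats.chi2_contingency(table, correction=False)
    else:
        p = 1.0
    return {
        "fa1": fa1,
        "fa2": fa2,
        "fpd1": fpd1,
        "fpd2": fpd2,
        "delta_fa": fa2 - fa1,
        "delta_fpd": fpd2 - fpd1,
        "p": float(p),
    }
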