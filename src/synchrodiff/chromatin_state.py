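"""Differential histone-modification regions and enhancer grammar.

Differential regions come from sliding-window G-tests on pooled replicate
read counts, with the expected split proportional to library sizes:

    G = 2 * [a ln(a/e_a) + b ln(b/e_b)],   0 ln 0 = 0

BH-corrected windows passing |FC| >= 2 and adjusted p <= 0.01 are kept,
filtered for overlap with called peaks, merged when adjacent and
same-direction, and annotated with genes within 10 kb.

Enhancers are classified from the three marks: H3K4me1 intervals anchor
enhancer identity; absence of H3K27ac makes an anchor poised, an H3K27ac
intersection of more than ``se_threshold`` (3 kb) makes it a
super-enhancer, anything in between an active enhancer; active/super
anchors are proximal when they overlap H3K4me3, else distal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomicInterval, IntervalSet, intersect_bp
from .footprints import bh_adjust

ENHANCER_CLASSES = (
    "poised",
    "active_proximal",
    "active_distal",
    "super_proximal",
    "super_distal",
)


def g_statistic(a: float, b: float, lib1: float, lib2: float) -> float:
    """Likelihood-ratio G for one window's counts under two conditions.

    Expected counts split the pooled total proportionally to the library
    sizes; 0 ln 0 is taken as 0.
    """
    total = a + b
    if total == 0:
        return 0.0
    ea = total * lib1 / (lib1 + lib2)
    eb = total * lib2 / (lib1 + lib2)
    g = 0.0
    if a > 0:
        g += a * np.log(a / ea)
    if b > 0:
        g += b * np.log(b / eb)
    return 2.0 * g


def _window_counts(reads: pd.DataFrame, chrom: str, starts: np.ndarray, window: int) -> np.ndarray:
    """Reads whose fragment midpoint falls inside each window."""
    sub = reads[reads.chrom == chrom]
    mids = np.sort(((sub.start + sub.end) // 2).to_numpy())
    lo = np.searchsorted(mids, starts)
    hi = np.searchsorted(mids, starts + window)
    return (hi - lo).astype(float)


def diff_histone_gtest(
    reads_c1: pd.DataFrame,
    reads_c2: pd.DataFrame,
    peaks_c1: IntervalSet,
    peaks_c2: IntervalSet,
    chrom_lengths: dict[str, int],
    window: int = 1000,
    step: int = 100,
    fc_min: float = 2.0,
    alpha: float = 0.01,
    gene_table: pd.DataFrame | None = None,
    gene_window: int = 10_000,
    mark: str = "",
) -> pd.DataFrame:
    """Sliding-window G-test differential regions between two conditions.

    Replicates are pooled per condition before counting. Windows without a
    read in either condition are not tested. Returns merged significant
    regions with the summed G statistic, the library-normalised fold change
    (condition2 / condition1), direction, and nearby genes.
    """
    lib1, lib2 = len(reads_c1), len(reads_c2)
    if lib1 == 0 or lib2 == 0:
        raise ValueError("zero library size")
    peak_union = IntervalSet(list(peaks_c1) + list(peaks_c2)).merge()

    rows = []
    for chrom, n in chrom_lengths.items():
        starts = np.arange(0, max(n - window + 1, 1), step)
        a = _window_counts(reads_c1, chrom, starts, window)
        b = _window_counts(reads_c2, chrom, starts, window)
        tested = (a + b) > 0
        for s, ai, bi in zip(starts[tested], a[tested], b[tested]):
            g = g_statistic(ai, bi, lib1, lib2)
            rows.append({"chrom": chrom, "start": int(s), "end": int(s + window), "a": ai, "b": bi, "g": g})
    if not rows:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "mark", "g_stat", "fc", "p_adj", "direction", "genes"]
        )
    win = pd.DataFrame(rows)
    win["p"] = stats.chi2.sf(win.g, df=1)
    win["p_adj"] = bh_adjust(win.p.to_numpy())
    pseudo = 0.5
    rate1 = (win.a + pseudo) / lib1
    rate2 = (win.b + pseudo) / lib2
    ratio = rate2 / rate1
    win["fc"] = ratio
    win["direction"] = np.where(ratio >= 1.0, "up", "down")

    sig = win[
        (win.p_adj <= alpha) & ((win.fc >= fc_min) | (win.fc <= 1.0 / fc_min))
    ].copy()
    if sig.empty:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "mark", "g_stat", "fc", "p_adj", "direction", "genes"]
        )

    # keep windows overlapping a called peak in either condition by >= 1 bp
    flat_peaks = peak_union
    keep = []
    for _, w in sig.iterrows():
        iv = IntervalSet([GenomicInterval(w.chrom, w.start, w.end)])
        keep.append(intersect_bp(iv, flat_peaks) > 0 or len(iv.overlapping(flat_peaks)) > 0)
    sig = sig[np.asarray(keep, dtype=bool)]
    if sig.empty:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "mark", "g_stat", "fc", "p_adj", "direction", "genes"]
        )

    # merge adjacent/overlapping significant same-direction windows
    merged = []
    for direction, grp in sig.groupby("direction"):
        grp = grp.sort_values(["chrom", "start"])
        cur = None
        for _, w in grp.iterrows():
            if (
                cur is not None
                and w.chrom == cur["chrom"]
                and w.start <= cur["end"]
            ):
                cur["end"] = max(cur["end"], int(w.end))
                cur["g_stat"] += float(w.g)
                cur["p_adj"] = min(cur["p_adj"], float(w.p_adj))
                cur["fc_vals"].append(float(w.fc))
            else:
                if cur is not None:
                    merged.append(cur)
                cur = {
                    "chrom": w.chrom,
                    "start": int(w.start),
                    "end": int(w.end),
                    "g_stat": float(w.g),
                    "p_adj": float(w.p_adj),
                    "direction": direction,
                    "fc_vals": [float(w.fc)],
                }
        if cur is not None:
            merged.append(cur)
    out = pd.DataFrame(merged)
    out["fc"] = out.fc_vals.map(lambda v: float(np.exp(np.mean(np.log(v)))))
    out = out.drop(columns="fc_vals")
    out["mark"] = mark

    # gene annotation within 10 kb
    genes_col = []
    for _, r in out.iterrows():
        if gene_table is None:
            genes_col.append("")
            continue
        near = gene_table[
            (gene_table.chrom == r.chrom)
            & (gene_table.tss >= r.start - gene_window)
            & (gene_table.tss <= r.end + gene_window)
        ]
        genes_col.append(",".join(near.gene_id))
    out["genes"] = genes_col
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)[
        ["chrom", "start", "end", "mark", "g_stat", "fc", "p_adj", "direction", "genes"]
    ]


def classify_enhancers(
    k27ac: IntervalSet,
    k4me1: IntervalSet,
    k4me3: IntervalSet,
    se_threshold: int = 3000,
    time_point: int | None = None,
) -> pd.DataFrame:
    """Classify each H3K4me1 anchor into the five enhancer classes.

    Intersection length is the total bp of H3K27ac overlap within the
    anchor (summed over fragments); exactly ``se_threshold`` bp is still
    'active' (strict > for super). Classes partition the anchor set.
    """
    rows = []
    for anchor in k4me1:
        a = IntervalSet([anchor])
        inter = intersect_bp(a, k27ac)
        if inter == 0:
            cls = "poised"
        else:
            size = "super" if inter > se_threshold else "active"
            prox = "proximal" if len(a.overlapping(k4me3)) else "distal"
            cls = f"{size}_{prox}"
        rows.append(
            {
                "chrom": anchor.chrom,
                "start": anchor.start,
                "end": anchor.end,
                "class": cls,
                "intersection": inter,
                "time_point": time_point,
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "class", "intersection", "time_point"]
    )


def _class_sets(records: pd.DataFrame) -> dict[str, IntervalSet]:
    out = {}
    for cls, grp in records.groupby("class"):
        out[cls] = IntervalSet(
            GenomicInterval(r.chrom, r.start, r.end) for _, r in grp.iterrows()
        )
    return out


def enhancer_dynamics(records_by_time: dict[int, pd.DataFrame]) -> dict:
    """Class dynamics across time points.

    Returns the Jaccard matrix over all (class, time) interval sets, the
    per-transition count of poised anchors converting to active/super, and
    the fraction of later super-enhancers already present earlier (subset
    fraction).
    """
    from .core import jaccard_cluster

    times = sorted(records_by_time)
    if len(times) < 2:
        raise ValueError("need at least two time points")
    named: dict[str, IntervalSet] = {}
    for t in times:
        for cls, ivset in _class_sets(records_by_time[t]).items():
            named[f"{cls}@{t}"] = ivset
    if len(named) >= 2:
        linkage_tree, ji = jaccard_cluster(named)
    else:
        linkage_tree, ji = None, pd.DataFrame()

    conversions = {}
    se_subset = {}
    for t0, t1 in zip(times[:-1], times[1:]):
        sets0 = _class_sets(records_by_time[t0])
        sets1 = _class_sets(records_by_time[t1])
        poised = sets0.get("poised", IntervalSet())
        active_later = IntervalSet(
            iv
            for cls in ("active_proximal", "active_distal", "super_proximal", "super_distal")
            for iv in sets1.get(cls, IntervalSet())
        )
        conversions[(t0, t1)] = len(poised.overlapping(active_later))
        se0 = IntervalSet(
            iv for cls in ("super_proximal", "super_distal") for iv in sets0.get(cls, IntervalSet())
        )
        se1 = IntervalSet(
            iv for cls in ("super_proximal", "super_distal") for iv in sets1.get(cls, IntervalSet())
        )
        se_subset[(t0, t1)] = (
            len(se1.overlapping(se0)) / len(se1) if len(se1) else float("nan")
        )
    return {"jaccard": ji, "linkage": linkage_tree, "poised_to_active": conversions, "se_subset_fraction": se_subset}


def overlap_expression_association(
    k4me1_up: IntervalSet,
    k27ac_up: IntervalSet,
    expr_fc: pd.Series,
    tss_table: pd.DataFrame,
    window: int = 10_000,
) -> dict:
    """Association between co-increased mark overlap length and expression.

    Co-increased loci are the direct intersections of the two increased
    sets; each gene with a TSS within ``window`` of a locus is assigned the
    total overlap length of its nearby loci, and the Spearman rank
    correlation with the expression change is reported.
    """
    loci = []
    for iv in k4me1_up:
        a = IntervalSet([iv])
        inter = intersect_bp(a, k27ac_up)
        if inter > 0:
            loci.append((iv.chrom, iv.start, iv.end, inter))
    if not loci:
        return {"table": pd.DataFrame(columns=["gene_id", "overlap", "expr_fc"]), "rho": float("nan"), "p": float("nan")}
    rows = []
    for _, g in tss_table.iterrows():
        if g.gene_id not in expr_fc.index:
            continue
        total = sum(
            l
            for c, s, e, l in loci
            if c == g.chrom and s - window <= g.tss <= e + window
        )
        if total > 0:
            rows.append({"gene_id": g.gene_id, "overlap": total, "expr_fc": float(expr_fc[g.gene_id])})
    table = pd.DataFrame(rows)
    if len(table) < 3:
        return {"table": table, "rho": float("nan"), "p": float("nan")}
    rho, p = stats.spearmanr(table.overlap, table.expr_fc)
    return {"table": table, "rho": float(rho), "p": float(p)}
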