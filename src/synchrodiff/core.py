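"""Core genomic primitives: intervals, signal tracks, reads and insertions.

All coordinates are 0-based half-open (BED convention). Every downstream
stage — differential accessibility, footprinting, enhancer classification —
is built on the small algebra defined here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval`.

    Intervals are kept sorted by (chrom, start, end). The set may contain
    overlapping intervals; :meth:`merge` produces a flattened version.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        self.intervals: list[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def total_bp(self) -> int:
        """Total covered base pairs after flattening overlaps."""
        return sum(e - s for _, s, e in _flatten(self.intervals))

    def merge(self, max_gap: int = 0) -> "IntervalSet":
        """Merge intervals whose gap is strictly below ``max_gap``.

        ``max_gap=0`` flattens only book-ended/overlapping intervals;
        ``max_gap=40`` merges intervals closer than 40 bp, i.e. gaps of
        at most 39 bp.
        """
        if max_gap < 0:
            raise ValueError("max_gap must be non-negative")
        out: list[GenomicInterval] = []
        for iv in self.intervals:
            if (
                out
                and out[-1].chrom == iv.chrom
                and iv.start - out[-1].end < max(max_gap, 1)
            ):
                prev = out.pop()
                out.append(
                    GenomicInterval(prev.chrom, prev.start, max(prev.end, iv.end))
                )
            else:
                out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
        return IntervalSet(out)

    def subtract_blacklist(self, blacklist: "IntervalSet") -> "IntervalSet":
        """Remove whole intervals overlapping the blacklist by >= 1 bp."""
        black = _flatten(blacklist.intervals)
        kept = [
            iv
            for iv in self.intervals
            if not _hits(black, iv.chrom, iv.start, iv.end)
        ]
        return IntervalSet(kept)

    def overlapping(self, other: "IntervalSet") -> "IntervalSet":
        """Subset of this set's intervals overlapping ``other`` by >= 1 bp."""
        flat = _flatten(other.intervals)
        return IntervalSet(
            iv for iv in self.intervals if _hits(flat, iv.chrom, iv.start, iv.end)
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "strand": [iv.strand for iv in self.intervals],
            }
        )


def _flatten(intervals: Sequence[GenomicInterval]) -> list[tuple[str, int, int]]:
    """Sorted, non-overlapping (chrom, start, end) triples covering the set."""
    out: list[tuple[str, int, int]] = []
    for iv in sorted(intervals, key=lambda v: (v.chrom, v.start, v.end)):
        if out and out[-1][0] == iv.chrom and iv.start <= out[-1][2]:
            c, s, e = out.pop()
            out.append((c, s, max(e, iv.end)))
        else:
            out.append((iv.chrom, iv.start, iv.end))
    return out


def _hits(flat: Sequence[tuple[str, int, int]], chrom: str, start: int, end: int) -> bool:
    """Binary-search test for >=1 bp overlap against a flattened set."""
    import bisect

    keys = [(c, s) for c, s, _ in flat]
    i = bisect.bisect_right(keys, (chrom, start))
    # candidate to the left may span start; candidate at i may begin before end
    if i > 0:
        c, s, e = flat[i - 1]
        if c == chrom and e > start:
            return True
    if i < len(flat):
        c, s, e = flat[i]
        if c == chrom and s < end:
            return True
    return False


def intersect_bp(a: IntervalSet, b: IntervalSet) -> int:
    """Total base pairs in the intersection of two interval sets."""
    fa, fb = _flatten(a.intervals), _flatten(b.intervals)
    total = 0
    i = j = 0
    while i < len(fa) and j < len(fb):
        ca, sa, ea = fa[i]
        cb, sb, eb = fb[j]
        if ca < cb or (ca == cb and ea <= sb):
            i += 1
        elif cb < ca or (ca == cb and eb <= sa):
            j += 1
        else:
            total += min(ea, eb) - max(sa, sb)
            if ea <= eb:
                i += 1
            else:
                j += 1
    return total


def jaccard_index(a: IntervalSet, b: IntervalSet) -> float:
    """Base-pair Jaccard index bp(A∩B)/bp(A∪B); 0/0 is defined as 0."""
    inter = intersect_bp(a, b)
    union = a.total_bp() + b.total_bp() - inter
    return inter / union if union > 0 else 0.0


def jaccard_matrix(sets: Mapping[str, IntervalSet]) -> pd.DataFrame:
    names = list(sets)
    n = len(names)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = jaccard_index(sets[names[i]], sets[names[j]])
    return pd.DataFrame(m, index=names, columns=names)


def jaccard_cluster(
    sets: Mapping[str, IntervalSet], method: str = "average"
) -> tuple[np.ndarray, pd.DataFrame]:
    """Hierarchical clustering of interval sets on distance 1 - Jaccard.

    Returns the scipy linkage matrix and the Jaccard-index matrix.
    """
    if len(sets) < 2:
        raise ValueError("need at least two interval sets to cluster")
    ji = jaccard_matrix(sets)
    dist = 1.0 - ji.to_numpy()
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method=method)
    return z, ji


# ---------------------------------------------------------------------------
# Reads, insertions and signal tracks
# ---------------------------------------------------------------------------

READ_COLUMNS = ["chrom", "start", "end", "strand", "mapq"]


def read_alignment_table(path, min_mapq: int = 0) -> pd.DataFrame:
    """Read a TSV alignment table (chrom, start, end, strand, mapq).

    A plain-text surrogate for BAM input; rows below ``min_mapq`` are
    dropped at ingest.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=READ_COLUMNS, comment="#")
    bad = df[(df.end <= df.start) | (df.start < 0)]
    if len(bad):
        raise ValueError(f"invalid read coordinates at row {bad.index[0]}")
    return df[df.mapq >= min_mapq].reset_index(drop=True)


def tn5_insertions(reads: pd.DataFrame) -> pd.DataFrame:
    """Convert aligned reads to Tn5 transposition sites.

    The transposase cut site is offset from the read 5' end: +4 bp on the
    forward strand and -5 bp from the 5' end of reverse-strand reads (the
    last aligned base, ``end - 1``, under half-open coordinates).
    Returns a DataFrame with columns chrom, pos, strand.
    """
    if (~reads.strand.isin(["+", "-"])).any():
        raise ValueError("unstranded read cannot be converted to an insertion")
    fwd = reads.strand == "+"
    pos = np.where(fwd, reads.start + 4, reads.end - 1 - 5)
    return pd.DataFrame(
        {"chrom": reads.chrom.to_numpy(), "pos": pos, "strand": reads.strand.to_numpy()}
    )


class SignalTrack:
    """Per-base signal vectors keyed by chromosome."""

    def __init__(self, values: Mapping[str, np.ndarray], library_size: int | None = None):
        self.values = {c: np.asarray(v, dtype=float) for c, v in values.items()}
        self.library_size = library_size

    def region(self, iv: GenomicInterval) -> np.ndarray:
        v = self.values[iv.chrom]
        return v[iv.start : min(iv.end, len(v))]

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    @classmethod
    def zeros(cls, chrom_lengths: Mapping[str, int]) -> "SignalTrack":
        return cls({c: np.zeros(n) for c, n in chrom_lengths.items()})


def coverage_track(
    reads: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    extend_to: int,
    normalise: bool = True,
    library_size: int | None = None,
) -> SignalTrack:
    """Per-base read coverage after 5'-anchored extension.

    Each read is extended from its 5' end to ``extend_to`` bp in the read
    orientation; extensions past a chromosome boundary are clipped with a
    single warning. With ``normalise`` the depth is scaled to reads per
    million (1e6 / number of reads).
    """
    if extend_to < 1:
        raise ValueError("extend_to must be >= 1")
    track = {c: np.zeros(n) for c, n in chrom_lengths.items()}
    clipped = False
    for chrom, grp in reads.groupby("chrom", sort=False):
        if chrom not in track:
            raise KeyError(f"read on unknown chromosome {chrom!r}")
        n = len(track[chrom])
        fwd = grp.strand.to_numpy() == "+"
        starts = np.where(fwd, grp.start.to_numpy(), grp.end.to_numpy() - extend_to)
        ends = starts + extend_to
        if (starts < 0).any() or (ends > n).any():
            clipped = True
        starts = np.clip(starts, 0, n)
        ends = np.clip(ends, 0, n)
        diff = np.zeros(n + 1)
        np.add.at(diff, starts, 1.0)
        np.add.at(diff, ends, -1.0)
        track[chrom] = np.cumsum(diff[:-1])
    if clipped:
        warnings.warn("read extension clipped at chromosome boundary", stacklevel=2)
    library = library_size if library_size is not None else len(reads)
    out = SignalTrack(track, library_size=library)
    if normalise and library > 0:
        for c in out.values:
            out.values[c] *= 1e6 / library
    return out


def insertion_track(
    insertions: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    normalise: bool = False,
) -> SignalTrack:
    """Per-base Tn5 insertion counts (optionally per-million normalised)."""
    track = {c: np.zeros(n) for c, n in chrom_lengths.items()}
    for chrom, grp in insertions.groupby("chrom", sort=False):
        if chrom not in track:
            raise KeyError(f"insertion on unknown chromosome {chrom!r}")
        pos = grp.pos.to_numpy()
        pos = pos[(pos >= 0) & (pos < len(track[chrom]))]
        np.add.at(track[chrom], pos, 1.0)
    out = SignalTrack(track, library_size=len(insertions))
    if normalise and len(insertions) > 0:
        for c in out.values:
            out.values[c] *= 1e6 / len(insertions)
    return out


def binned_signal(track: SignalTrack, region: GenomicInterval, n_bins: int) -> np.ndarray:
    """Mean per-base signal in ``n_bins`` equal-width bins across a region.

    When the region length is not divisible by ``n_bins`` the remainder
    bases are assigned one per bin from the left, keeping bin widths
    deterministic.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    length = len(region)
    if length < n_bins:
        raise ValueError(f"region of {length} bp cannot hold {n_bins} bins")
    sig = track.region(region)
    if len(sig) < length:  # region runs past chromosome end
        sig = np.concatenate([sig, np.zeros(length - len(sig))])
    base, rem = divmod(length, n_bins)
    widths = np.full(n_bins, base, dtype=int)
    widths[:rem] += 1
    edges = np.concatenate([[0], np.cumsum(widths)])
    return np.array(
        [sig[edges[i] : edges[i + 1]].mean() for i in range(n_bins)]
    )


# ---------------------------------------------------------------------------
# BED / bedGraph / FASTA I/O
# ---------------------------------------------------------------------------


def read_bed(path) -> IntervalSet:
    """Read BED3/BED6 into an IntervalSet; track/browser lines are skipped."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}")
            try:
                start, end = int(parts[1]), int(parts[2])
                strand = parts[5] if len(parts) >= 6 and parts[5] in STRANDS else "."
                intervals.append(GenomicInterval(parts[0], start, end, strand))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return IntervalSet(intervals)


def write_bed(intervals: IntervalSet, path, extra: pd.DataFrame | None = None) -> None:
    df = intervals.to_dataframe()
    if extra is not None:
        df = pd.concat([df.reset_index(drop=True), extra.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path, chrom_lengths: Mapping[str, int]) -> SignalTrack:
    """Read a bedGraph as a piecewise-constant per-base SignalTrack."""
    track = SignalTrack.zeros(chrom_lengths)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: malformed bedGraph line {lineno}")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if end <= start:
                raise ValueError(f"{path}: line {lineno}: end <= start")
            v = track.values[chrom]
            v[start : min(end, len(v))] = value
    return track


def write_bedgraph(track: SignalTrack, path) -> None:
    """Write a SignalTrack as run-length-compressed bedGraph (zeros skipped)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            v = track.values[chrom]
            if not len(v):
                continue
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(v)]])
            for s, e in zip(starts, ends):
                if v[s] != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v[s]:g}\n")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into a dict of uppercase sequences."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None and line:
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
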