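"""Cleavage-site calling from 3'-end read counts and sequence motif scans.

Covers the three sequence features that mark a functional polyadenylation
site: the PAS hexamer (canonical AAUAAA or a single-mismatch variant such as
AUUAAA) 10-40 nt upstream of cleavage, the G/U-rich element just downstream,
and — for the trans-acting side — the bipartite QKI recognition element
5'-NACUAAY-N(1,20)-UAAY-3' (Y = C/U, N = any base).

Sequences may be DNA or RNA; T is treated as U throughout.  Positions are
0-based indices into the supplied sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .regions import GenomicInterval

__all__ = [
    "EndCountTrack",
    "CleavageSite",
    "PASMatch",
    "QKIMatch",
    "CANONICAL_PAS",
    "call_end_peaks",
    "scan_pas",
    "scan_gu_rich",
    "scan_qki_motif",
    "reverse_complement",
]

CANONICAL_PAS = "AAUAAA"

_COMPLEMENT = str.maketrans("ACGUTN", "UGCAAN")


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def reverse_complement(seq: str) -> str:
    return _rna(seq).translate(_COMPLEMENT)[::-1]


@dataclass
class EndCountTrack:
    """Per-base counts of read 3' ends over a genomic interval."""

    interval: GenomicInterval
    end_counts: np.ndarray

    def __post_init__(self) -> None:
        self.end_counts = np.asarray(self.end_counts)
        if len(self.end_counts) != len(self.interval):
            raise ValueError("end_counts length does not match interval")
        if np.any(self.end_counts < 0):
            raise ValueError("negative end counts")


@dataclass(frozen=True)
class PASMatch:
    hexamer: str
    offset: int  # bases upstream of the cleavage position (summit)
    pas_class: str  # "canonical" | "variant"


@dataclass(frozen=True)
class GUMatch:
    present: bool
    score: float  # best window G/U fraction
    flag: str = ""


@dataclass
class CleavageSite:
    summit: int  # genomic position (0-based) of the max end count
    total_count: int
    span: GenomicInterval
    pas_hit: PASMatch | None = None
    gu_rich: GUMatch | None = None


@dataclass(frozen=True)
class QKIMatch:
    half1_start: int  # start of NACUAAY
    spacer_len: int  # 1..20
    half2_start: int  # start of UAAY == half1_start + 7 + spacer_len


def call_end_peaks(track: EndCountTrack, min_count: int = 10,
                   merge_window: int = 8) -> list[CleavageSite]:
    """Greedy clustering of 3'-end positions into cleavage sites.

    Non-zero positions within ``merge_window`` of the previous non-zero
    position join the same cluster; clusters totalling fewer than
    ``min_count`` reads are discarded.  The summit is the argmax position,
    ties broken toward the most 3' position in transcript direction
    (matching the sharp 3' cliff of real cleavage signal).  Output is
    sorted 5'->3'.
    """
    if min_count < 1 or merge_window < 0:
        raise ValueError("require min_count >= 1 and merge_window >= 0")
    counts = np.asarray(track.end_counts)
    nz = np.flatnonzero(counts)
    if len(nz) == 0:
        return []
    clusters: list[list[int]] = [[nz[0]]]
    for idx in nz[1:]:
        if idx - clusters[-1][-1] <= merge_window:
            clusters[-1].append(idx)
        else:
            clusters.append([idx])
    iv = track.interval
    minus = iv.strand == "-"
    sites = []
    for idxs in clusters:
        idxs = np.asarray(idxs)
        total = int(counts[idxs].sum())
        if total < min_count:
            continue
        best = counts[idxs].max()
        at_max = idxs[counts[idxs] == best]
        # most 3' in transcript direction: highest genomic index on +,
        # lowest on -
        summit_idx = int(at_max.min() if minus else at_max.max())
        span = GenomicInterval(
            iv.chrom, iv.start + int(idxs.min()), iv.start + int(idxs.max()) + 1,
            iv.strand,
        )
        sites.append(
            CleavageSite(summit=iv.start + summit_idx, total_count=total, span=span)
        )
    # 5'->3' in transcript direction
    sites.sort(key=lambda s: -s.summit if minus else s.summit)
    return sites


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def scan_pas(seq: str, cleavage_pos: int, window_upstream: int = 40) -> list[PASMatch]:
    """All PAS hexamers within ``window_upstream`` nt upstream of cleavage.

    Reports every 6-mer starting in ``[cleavage_pos - window_upstream,
    cleavage_pos)`` (clipped to the sequence) at Hamming distance <= 1 from
    AAUAAA: the canonical hexamer first, then variants ordered by ascending
    distance from the cleavage position.
    """
    s = _rna(seq)
    if len(s) < 6:
        return []
    lo = max(0, cleavage_pos - window_upstream)
    hi = min(cleavage_pos, len(s) - 5)
    hits = []
    for start in range(lo, hi):
        hexamer = s[start : start + 6]
        dist = _hamming(hexamer, CANONICAL_PAS)
        if dist <= 1:
            hits.append(
                PASMatch(
                    hexamer=hexamer,
                    offset=cleavage_pos - start,
                    pas_class="canonical" if dist == 0 else "variant",
                )
            )
    hits.sort(key=lambda m: (m.pas_class != "canonical", m.offset))
    return hits


def scan_gu_rich(seq: str, cleavage_pos: int, window_downstream: int = 40,
                 min_frac: float = 0.6, min_len: int = 10) -> GUMatch:
    """Best G/U fraction over sliding windows downstream of the cleavage site."""
    if window_downstream <= 0 or min_len <= 0:
        raise ValueError("window parameters must be positive")
    s = _rna(seq)
    region = s[cleavage_pos : cleavage_pos + window_downstream]
    if len(region) < min_len:
        return GUMatch(False, 0.0, flag="downstream sequence absent")
    is_gu = np.frombuffer(region.encode(), dtype=np.uint8)
    is_gu = ((is_gu == ord("G")) | (is_gu == ord("U"))).astype(np.int64)
    csum = np.concatenate(([0], np.cumsum(is_gu)))
    window_sums = csum[min_len:] - csum[:-min_len]
    score = int(window_sums.max()) / min_len
    return GUMatch(score >= min_frac, score)


def _is_qki_half1(s: str, i: int) -> bool:
    # NACUAAY
    return (
        i + 7 <= len(s)
        and s[i + 1 : i + 6] == "ACUAA"
        and s[i + 6] in "CU"
    )


def _is_qki_half2(s: str, i: int) -> bool:
    # UAAY
    return i + 4 <= len(s) and s[i : i + 3] == "UAA" and s[i + 3] in "CU"


def scan_qki_motif(seq: str, exhaustive: bool = False) -> list[QKIMatch]:
    """Find the bipartite QKI element NACUAAY-N(1,20)-UAAY.

    Default policy pairs each NACUAAY half-site with the *nearest* valid
    downstream UAAY (spacer 1-20), greedily left to right, never reusing
    bases already claimed by an accepted match's half-sites.  In
    ``exhaustive`` mode every valid (half1, spacer) pairing is reported.
    """
    s = _rna(seq)
    matches: list[QKIMatch] = []
    if exhaustive:
        for i in range(len(s)):
            if not _is_qki_half1(s, i):
                continue
            for spacer in range(1, 21):
                j = i + 7 + spacer
                if j + 4 > len(s):
                    break
                if _is_qki_half2(s, j):
                    matches.append(QKIMatch(i, spacer, j))
        return matches
    claimed: list[tuple[int, int]] = []  # half-site spans of accepted matches

    def free(a: int, b: int) -> bool:
        return all(b <= lo or a >= hi for lo, hi in claimed)

    for i in range(len(s)):
        if not _is_qki_half1(s, i) or not free(i, i + 7):
            continue
        for spacer in range(1, 21):
            j = i + 7 + spacer
            if j + 4 > len(s):
                break
            if _is_qki_half2(s, j) and free(j, j + 4):
                matches.append(QKIMatch(i, spacer, j))
                claimed.extend([(i, i + 7), (j, j + 4)])
                break
    return matches
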