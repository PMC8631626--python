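"""Strand-aware interval types, coordinate mapping, and coverage/region I/O.

All internal coordinates are 0-based half-open on the + reference strand.
Transcript coordinates are 1-based inclusive (the convention of RefSeq-style
accession annotations such as NM_000295).  Published SERPINA1 3'UTR region
coordinates are 1-based inclusive and, on the minus strand, listed in
descending genomic order; they are converted at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomicInterval",
    "TranscriptInterval",
    "RegionSpec",
    "CoverageTrack",
    "map_transcript_to_genomic",
    "map_genomic_to_transcript",
    "interval_length",
    "printed_span_length",
    "read_coverage",
    "write_bedgraph",
    "read_region_spec_bed",
    "write_region_spec_bed",
    "serpina1_region_spec",
    "serpina1_printed_table",
    "validate_printed_table",
    "SERPINA1_ANCHOR",
]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on the + reference strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(
                f"require start < end, got [{self.start}, {self.end})"
            )
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TranscriptInterval:
    """1-based inclusive interval in transcript coordinates."""

    transcript_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"require 1 <= start <= end, got {self.start}..{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


def interval_length(iv) -> int:
    """Length in bases of either interval flavor."""
    return len(iv)


def printed_span_length(a: int, b: int) -> int:
    """Length of a published 1-based inclusive span given in either order.

    Minus-strand tables often list coordinates in descending genomic order
    (e.g. chr14:94378451-94378373); the length is |a - b| + 1 regardless.
    """
    return abs(a - b) + 1


def map_transcript_to_genomic(
    t_iv: TranscriptInterval,
    anchor_transcript_pos: int,
    anchor_genomic_pos: int,
    strand: str,
    chrom: str,
) -> GenomicInterval:
    """Map a transcript interval to genomic coordinates through an anchor.

    The anchor pairs a 1-based transcript position with the 1-based genomic
    position of that same nucleotide.  Single-exon mapping only: for the +
    strand g = anchor_g + (t - anchor_t); for the - strand
    g = anchor_g - (t - anchor_t).  The result is returned 0-based half-open
    with start < end; interval length is preserved exactly.
    """
    if strand == "+":
        g1 = anchor_genomic_pos + (t_iv.start - anchor_transcript_pos)
        g2 = anchor_genomic_pos + (t_iv.end - anchor_transcript_pos)
    elif strand == "-":
        g1 = anchor_genomic_pos - (t_iv.start - anchor_transcript_pos)
        g2 = anchor_genomic_pos - (t_iv.end - anchor_transcript_pos)
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    lo, hi = min(g1, g2), max(g1, g2)
    if lo < 1:
        raise ValueError(
            f"mapped genomic coordinate {lo} is non-positive for {t_iv}"
        )
    return GenomicInterval(chrom, lo - 1, hi, strand)


def map_genomic_to_transcript(
    g_iv: GenomicInterval,
    anchor_transcript_pos: int,
    anchor_genomic_pos: int,
    transcript_id: str,
) -> TranscriptInterval:
    """Inverse of :func:`map_transcript_to_genomic` (single-exon)."""
    first_base = g_iv.start + 1  # 1-based genomic position of lowest base
    last_base = g_iv.end
    if g_iv.strand == "+":
        t1 = anchor_transcript_pos + (first_base - anchor_genomic_pos)
        t2 = anchor_transcript_pos + (last_base - anchor_genomic_pos)
    else:
        t1 = anchor_transcript_pos + (anchor_genomic_pos - last_base)
        t2 = anchor_transcript_pos + (anchor_genomic_pos - first_base)
    return TranscriptInterval(transcript_id, min(t1, t2), max(t1, t2))


@dataclass(frozen=True)
class RegionSpec:
    """Proximal/distal 3'UTR intervals plus optional named subregions.

    Invariants enforced at construction: proximal and distal do not overlap,
    and in transcript (5'->3') direction the distal interval lies downstream
    of the proximal one.  Subregion tiling of the distal interval is checked
    by :meth:`validate`, which *reports* problems rather than raising: real
    published coordinate tables contain off-by-one inconsistencies that must
    not be silently repaired.
    """

    gene: str
    strand: str
    proximal: GenomicInterval
    distal: GenomicInterval
    subregions: dict[str, GenomicInterval] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.proximal.overlaps(self.distal):
            raise ValueError("proximal and distal intervals overlap")
        if self.proximal.chrom != self.distal.chrom:
            raise ValueError("proximal and distal on different chromosomes")
        # downstream = 3' in transcript direction: higher genomic coordinates
        # on the + strand, lower on the - strand.
        if self.strand == "+":
            downstream_ok = self.distal.start >= self.proximal.end
        else:
            downstream_ok = self.distal.end <= self.proximal.start
        if not downstream_ok:
            raise ValueError(
                "distal interval is not downstream of proximal in "
                "transcript direction"
            )

    @property
    def span(self) -> GenomicInterval:
        """Genomic hull covering both regions."""
        return GenomicInterval(
            self.proximal.chrom,
            min(self.proximal.start, self.distal.start),
            max(self.proximal.end, self.distal.end),
            self.strand,
        )

    def validate(self) -> list[str]:
        """Return a list of human-readable issues (empty when clean)."""
        issues: list[str] = []
        if not self.subregions:
            return issues
        ivs = sorted(self.subregions.items(), key=lambda kv: kv[1].start)
        covered = 0
        prev_name, prev = None, None
        for name, iv in ivs:
            if iv.chrom != self.distal.chrom:
                issues.append(f"{name}: wrong chromosome {iv.chrom}")
                continue
            if iv.start < self.distal.start or iv.end > self.distal.end:
                issues.append(f"{name}: extends outside the distal interval")
            if prev is not None:
                if iv.start < prev.end:
                    issues.append(f"{prev_name}/{name}: overlap by {prev.end - iv.start} nt")
                elif iv.start > prev.end:
                    issues.append(f"{prev_name}/{name}: gap of {iv.start - prev.end} nt")
            covered += len(iv)
            prev_name, prev = name, iv
        if ivs and ivs[0][1].start != self.distal.start:
            issues.append("subregions do not start at the distal boundary")
        if ivs and ivs[-1][1].end != self.distal.end:
            issues.append("subregions do not end at the distal boundary")
        return issues


@dataclass
class CoverageTrack:
    """Per-base read depth over a contiguous genomic interval."""

    interval: GenomicInterval
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 1 or len(self.depth) != len(self.interval):
            raise ValueError(
                f"depth length {len(self.depth)} does not match interval "
                f"length {len(self.interval)}"
            )
        if np.any(self.depth < 0):
            raise ValueError("negative depth values")

    def slice(self, iv: GenomicInterval) -> np.ndarray:
        """Depth values over a sub-interval of the track."""
        if not self.interval.contains(iv):
            raise ValueError(f"{iv} not contained in track {self.interval}")
        off = iv.start - self.interval.start
        return self.depth[off : off + len(iv)]


# ---------------------------------------------------------------------------
# coverage I/O
# ---------------------------------------------------------------------------


def _round_value(value: str, lineno: int, strict: bool) -> int:
    try:
        v = float(value)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: malformed depth value {value!r}") from exc
    if v < 0:
        raise ValueError(f"line {lineno}: negative depth {v}")
    if v != int(v):
        if strict:
            raise ValueError(f"line {lineno}: non-integer depth {v} in strict mode")
        return int(round(v))
    return int(v)


def read_coverage(path, iv: GenomicInterval, fmt: str | None = None,
                  strict: bool = False) -> CoverageTrack:
    """Read per-base depth over ``iv`` from a bedGraph or position/depth TSV.

    bedGraph records are 0-based half-open ``chrom start end value``;
    the TSV alternative is two columns ``position depth`` with 1-based
    positions.  Bases absent from the source get depth 0.  Overlapping
    bedGraph records and duplicated TSV positions are rejected.  Fractional
    values are rounded to the nearest integer unless ``strict``.
    """
    path = str(path)
    if fmt is None:
        fmt = "bedgraph" if path.endswith((".bedgraph", ".bg", ".bedGraph")) else None
    depth = np.zeros(len(iv), dtype=np.int64)
    written = np.zeros(len(iv), dtype=bool)
    any_chrom_match = False
    with open(path) as fh:
        lines = [
            (i + 1, ln.rstrip("\n"))
            for i, ln in enumerate(fh)
            if ln.strip() and not ln.startswith(("#", "track", "browser"))
        ]
    if fmt is None:
        fmt = "bedgraph" if lines and len(lines[0][1].split()) >= 4 else "tsv"
    for lineno, line in lines:
        parts = line.split()
        if fmt == "bedgraph":
            if len(parts) < 4:
                raise ValueError(f"line {lineno}: expected 4 bedGraph columns")
            chrom, s, e, raw = parts[0], parts[1], parts[2], parts[3]
            if chrom != iv.chrom:
                continue
            any_chrom_match = True
            try:
                s, e = int(s), int(e)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: malformed coordinates") from exc
            if s >= e:
                raise ValueError(f"line {lineno}: empty or inverted record")
            v = _round_value(raw, lineno, strict)
            lo = max(s, iv.start)
            hi = min(e, iv.end)
            if lo >= hi:
                continue
            sl = slice(lo - iv.start, hi - iv.start)
            if written[sl].any():
                raise ValueError(f"line {lineno}: overlapping bedGraph records")
            depth[sl] = v
            written[sl] = True
        else:
            if len(parts) < 2:
                raise ValueError(f"line {lineno}: expected 2 TSV columns")
            try:
                pos = int(parts[0])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: malformed position") from exc
            any_chrom_match = True
            v = _round_value(parts[1], lineno, strict)
            idx = pos - 1 - iv.start  # 1-based position -> array index
            if not 0 <= idx < len(iv):
                continue
            if written[idx]:
                raise ValueError(f"line {lineno}: duplicate position {pos}")
            depth[idx] = v
            written[idx] = True
    if lines and not any_chrom_match:
        warnings.warn(
            f"no records on chromosome {iv.chrom}; returning all-zero track",
            stacklevel=2,
        )
    return CoverageTrack(iv, depth)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a coverage track as run-length-compressed bedGraph."""
    iv, d = track.interval, np.asarray(track.depth)
    with open(path, "w") as fh:
        if len(d) == 0:
            return
        change = np.flatnonzero(np.diff(d)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(d)]))
        for s, e in zip(starts, ends):
            if d[s] != 0:
                fh.write(f"{iv.chrom}\t{iv.start + s}\t{iv.start + e}\t{int(d[s])}\n")


# ---------------------------------------------------------------------------
# region spec I/O (BED6; the name field encodes the role)
# ---------------------------------------------------------------------------


def read_region_spec_bed(path, gene: str = "") -> RegionSpec:
    """Build a RegionSpec from BED6 with names proximal/distal/Region1..N."""
    proximal = distal = None
    subregions: dict[str, GenomicInterval] = {}
    strand = "+"
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"line {lineno}: expected BED6")
            chrom, s, e, name, _score, strand = parts[:6]
            iv = GenomicInterval(chrom, int(s), int(e), strand)
            key = name.lower()
            if key == "proximal":
                proximal = iv
            elif key == "distal":
                distal = iv
            else:
                subregions[name] = iv
    if proximal is None:
        raise ValueError("BED is missing a 'proximal' record")
    if distal is None:
        if not subregions:
            raise ValueError("BED is missing a 'distal' record")
        distal = GenomicInterval(
            proximal.chrom,
            min(iv.start for iv in subregions.values()),
            max(iv.end for iv in subregions.values()),
            strand,
        )
    return RegionSpec(gene, strand, proximal, distal, subregions)


def write_region_spec_bed(spec: RegionSpec, path) -> None:
    with open(path, "w") as fh:
        rows = [("proximal", spec.proximal), ("distal", spec.distal)]
        rows += list(spec.subregions.items())
        for name, iv in rows:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# SERPINA1 defaults
# ---------------------------------------------------------------------------

# The SERPINA1 3'UTR is a single exon on the minus strand of chr14.  The
# published region table anchors transcript position 1519 of NM_000295 at
# chr14:94378451 (1-based).
SERPINA1_ANCHOR = {
    "transcript_id": "NM_000295",
    "chrom": "chr14",
    "strand": "-",
    "anchor_transcript_pos": 1519,
    "anchor_genomic_pos": 94378451,
}

# Published rows: transcript interval (1-based inclusive) and the genomic
# coordinates exactly as printed (1-based inclusive, mostly in descending
# minus-strand order).  The printed genomic column is internally
# inconsistent with the transcript column (see validate_printed_table).
_SERPINA1_PRINTED = {
    "Proximal": ((1519, 1597), (94378451, 94378373)),
    "Region1": ((1619, 2016), (94377952, 94378350)),
    "Region2": ((2017, 2416), (94377953, 94377554)),
    "Region3": ((2417, 2816), (94377555, 94377156)),
    "Region4": ((2817, 3220), (94377157, 94376747)),
}


def serpina1_printed_table() -> dict[str, tuple[tuple[int, int], tuple[int, int]]]:
    """The published SERPINA1 region table: name -> (transcript, genomic)."""
    return dict(_SERPINA1_PRINTED)


def validate_printed_table(table=None) -> list[str]:
    """Report length mismatches between printed transcript and genomic spans.

    Printed coordinates are never silently corrected; this surfaces the
    discrepancies so the caller can decide which column to trust.
    """
    table = table or _SERPINA1_PRINTED
    issues = []
    for name, ((t1, t2), (g1, g2)) in table.items():
        lt = printed_span_length(t1, t2)
        lg = printed_span_length(g1, g2)
        if lt != lg:
            issues.append(
                f"{name}: transcript span {lt} nt but printed genomic span {lg} nt"
            )
    return issues


def serpina1_region_spec() -> RegionSpec:
    """Default SERPINA1 3'UTR RegionSpec.

    Built from the transcript-coordinate column mapped through the proximal
    anchor (the transcript column tiles exactly; the printed genomic column
    does not).  Proximal = the 79-nt proximal row; distal = the union of
    Regions 1-4 (1602 nt).
    """
    a = SERPINA1_ANCHOR
    ivs = {
        name: map_transcript_to_genomic(
            TranscriptInterval(a["transcript_id"], t1, t2),
            a["anchor_transcript_pos"],
            a["anchor_genomic_pos"],
            a["strand"],
            a["chrom"],
        )
        for name, ((t1, t2), _g) in _SERPINA1_PRINTED.items()
    }
    proximal = ivs.pop("Proximal")
    distal = GenomicInterval(
        a["chrom"],
        min(iv.start for iv in ivs.values()),
        max(iv.end for iv in ivs.values()),
        a["strand"],
    )
    return RegionSpec("SERPINA1", a["strand"], proximal, distal, ivs)
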