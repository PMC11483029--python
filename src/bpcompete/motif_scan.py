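"""Strand-aware 3'ss-proximal window extraction and degenerate motif scanning.

The scanner reports *all* matches, including mutually overlapping ones.  This
matters: a tandem-embedded site such as TACTAACTAAC carries two overlapping
ACTAA occurrences (offsets 1 and 5), and counting only non-overlapping
matches would miss the dual-site class entirely.

Windows are cut from intron sequence only, anchored on the last intron base
(the 3'ss-adjacent position), and returned 5'->3' in transcript orientation.
``WindowSpec(a, b)`` denotes the half-open transcript-oriented slice
``intron[len-a : len-b]`` — e.g. (80, 0) is the last 80 intron nucleotides,
(63, 20) the 43 nt ending 20 nt upstream of the 3'ss.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import GenomeSequence, IntronAnnotation, reverse_complement
from .stats_core import TestResult, chi_squared_2x2

__all__ = [
    "WindowSpec",
    "MotifPattern",
    "MotifHit",
    "QreCall",
    "extract_3ss_window",
    "scan_motif",
    "find_qre",
    "has_dual_core",
    "dual_motif_enrichment",
    "positional_motif_map",
    "CUSTOM_BP_MOTIFS",
]

# branchpoint-like / QKI-related custom patterns used for map scanning
CUSTOM_BP_MOTIFS = (
    "ACT[ACTG]AG",
    "[ACTG]CT[AG][CT]",
    "TAA[CT]",
    "TAA[CT]T[ACTG]A[CT]",
    "TACTAAC",
    "TACTAA",
    "ACTAA[CT]",
    "TACTAA[CT]",
    "CTAAC[ACG]",
)

_IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class WindowSpec:
    """Offsets (in nt upstream of the intron's 3' end) bounding a window.

    ``upstream_start > upstream_end >= 0``; the window length is their
    difference.  ``clamp_policy`` says what to do when the intron is shorter
    than ``upstream_start``: "truncate" keeps the available sequence,
    "skip" raises :class:`WindowSkipped`.
    """

    upstream_start: int
    upstream_end: int = 0
    clamp_policy: str = "truncate"

    def __post_init__(self) -> None:
        if not self.upstream_start > self.upstream_end >= 0:
            raise ValueError("need upstream_start > upstream_end >= 0")
        if self.clamp_policy not in ("truncate", "skip"):
            raise ValueError(f"unknown clamp policy {self.clamp_policy!r}")


class WindowSkipped(ValueError):
    """Raised under skip policy when an intron cannot fill the window."""


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate motif over IUPAC codes and [..] bracket classes.

    Compiled to one allowed-base set per position; ``N`` in the *sequence*
    never matches (pattern sets only ever contain ACGT).
    """

    pattern: str
    sets: tuple[frozenset[str], ...]

    @classmethod
    def compile(cls, pattern: str) -> "MotifPattern":
        sets: list[frozenset[str]] = []
        i = 0
        up = pattern.upper()
        while i < len(up):
            ch = up[i]
            if ch == "[":
                j = up.find("]", i)
                if j < 0:
                    raise ValueError(f"unclosed bracket in {pattern!r}")
                allowed: set[str] = set()
                for sym in up[i + 1 : j]:
                    if sym not in _IUPAC:
                        raise ValueError(f"bad symbol {sym!r} in {pattern!r}")
                    allowed |= _IUPAC[sym]
                sets.append(frozenset(allowed))
                i = j + 1
            else:
                if ch not in _IUPAC:
                    raise ValueError(f"bad symbol {ch!r} in {pattern!r}")
                sets.append(_IUPAC[ch])
                i += 1
        if len(sets) < 3:
            raise ValueError(f"pattern {pattern!r} shorter than 3 positions")
        return cls(pattern, tuple(sets))

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def regex(self) -> re.Pattern:
        # lookahead makes finditer report overlapping starts
        body = "".join("[" + "".join(sorted(s)) + "]" for s in self.sets)
        return re.compile(f"(?=({body}))")

    def reverse_complement(self) -> "MotifPattern":
        rc_sets = tuple(
            frozenset(_COMP[b] for b in s) for s in reversed(self.sets)
        )
        return MotifPattern(f"revcomp({self.pattern})", rc_sets)


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence: 0-based window offset and matched substring."""

    offset: int
    matched: str
    genomic: int | None = None


@dataclass(frozen=True)
class QreCall:
    """A bipartite Quaking response element: core + half-site within a gap."""

    core: MotifHit
    half_site: MotifHit
    gap: int
    orientation: str  # "5prime" or "3prime": half-site side relative to core


def _as_pattern(pattern: str | MotifPattern) -> MotifPattern:
    return pattern if isinstance(pattern, MotifPattern) else MotifPattern.compile(pattern)


def extract_3ss_window(
    genome: GenomeSequence | dict[str, GenomeSequence],
    intron: IntronAnnotation,
    spec: WindowSpec,
) -> str:
    """Cut the 3'ss-proximal window of an intron, transcript-oriented.

    Never crosses into flanking exons: the window is a slice of the intron
    itself.  For minus-strand introns the genomic slice is reverse
    complemented so the result always reads 5'->3' along the transcript.
    """
    chrom = genome[intron.chrom] if isinstance(genome, dict) else genome
    if chrom.name != intron.chrom:
        raise ValueError(f"intron {intron.intron_id} not on contig {chrom.name}")
    if intron.end > len(chrom):
        raise ValueError(f"intron {intron.intron_id} beyond contig bounds")
    ilen = intron.length
    start_off = spec.upstream_start
    if ilen < start_off:
        if spec.clamp_policy == "skip":
            raise WindowSkipped(
                f"{intron.intron_id}: intron ({ilen} nt) shorter than "
                f"window start offset {start_off}"
            )
        start_off = ilen
    if start_off <= spec.upstream_end:
        return ""
    tx_seq = chrom.sequence[intron.start : intron.end]
    if intron.strand == "-":
        tx_seq = reverse_complement(tx_seq)
    return tx_seq[ilen - start_off : ilen - spec.upstream_end]


def window_offset_to_genomic(
    intron: IntronAnnotation, spec: WindowSpec, offset: int
) -> int:
    """Genomic coordinate of window position ``offset`` (0-based)."""
    start_off = min(spec.upstream_start, intron.length)
    tx_pos = intron.length - start_off + offset  # position within intron
    if intron.strand == "+":
        return intron.start + tx_pos
    return intron.end - 1 - tx_pos


def scan_motif(sequence: str, pattern: str | MotifPattern) -> list[MotifHit]:
    """All occurrences of ``pattern`` in ``sequence``, overlaps included."""
    pat = _as_pattern(pattern)
    seq = sequence.upper().replace("U", "T")
    return [
        MotifHit(m.start(), m.group(1)) for m in pat.regex.finditer(seq)
    ]


def find_qre(
    sequence: str,
    core: str | MotifPattern = "ACTAA",
    halfsite: str | MotifPattern = "TAA[CT]",
    max_gap: int = 20,
) -> list[QreCall]:
    """Bipartite QRE calls: a core plus a half-site within ``max_gap`` nt.

    The gap is counted between the nearest pattern edges, on either side of
    the core.  Half-site hits lying fully inside a core hit are discarded
    (they are part of the core, not an independent half-site).
    """
    core_pat, half_pat = _as_pattern(core), _as_pattern(halfsite)
    cores = scan_motif(sequence, core_pat)
    halves = scan_motif(sequence, half_pat)
    calls = []
    for c in cores:
        c_start, c_end = c.offset, c.offset + len(core_pat)
        for h in halves:
            h_start, h_end = h.offset, h.offset + len(half_pat)
            if c_start <= h_start and h_end <= c_end:
                continue  # embedded in the core
            if h_start >= c_end:
                gap, orient = h_start - c_end, "3prime"
            elif h_end <= c_start:
                gap, orient = c_start - h_end, "5prime"
            else:
                gap = 0
                orient = "5prime" if h_start < c_start else "3prime"
            if gap <= max_gap:
                calls.append(QreCall(c, h, gap, orient))
    return calls


def has_dual_core(
    sequence: str, core: str | MotifPattern = "ACTAA"
) -> tuple[bool, int]:
    """True when >= 2 core occurrences (independent or tandem-embedded)."""
    count = len(scan_motif(sequence, core))
    return count >= 2, count


def dual_motif_enrichment(
    regulated_windows: Sequence[str],
    control_windows: Sequence[str],
    core: str | MotifPattern = "ACTAA",
    yates: bool = False,
) -> tuple[np.ndarray, TestResult]:
    """2x2 chi-squared test of dual-core prevalence, regulated vs control.

    Rows {regulated, control} x columns {dual-core, not}.  Returns the table
    alongside the test so the underlying counts are always inspectable.
    """
    if not len(regulated_windows) or not len(control_windows):
        raise ValueError("both window sets must be non-empty")
    a = sum(has_dual_core(w, core)[0] for w in regulated_windows)
    b = len(regulated_windows) - a
    c = sum(has_dual_core(w, core)[0] for w in control_windows)
    d = len(control_windows) - c
    table = np.array([[a, b], [c, d]], dtype=int)
    return table, chi_squared_2x2(a, b, c, d, yates=yates)


def positional_motif_map(
    fg_up_windows: Sequence[str],
    fg_down_windows: Sequence[str],
    bg_windows: Sequence[str],
    pattern: str | MotifPattern,
    window_len: int = 50,
    step: int = 1,
):
    """Sliding-window motif coverage around the 3'ss anchor.

    All sequences must share one length (they are 3'ss-anchored windows).
    For each sliding sub-window the per-set fraction of sequences with at
    least one fully contained hit is reported, plus a two-proportion
    chi-squared p-value of each foreground set against the background.
    Returns a pandas DataFrame with columns position, frac_up, frac_down,
    frac_bg, p_up, p_down.
    """
    import pandas as pd

    if not len(fg_up_windows) and not len(fg_down_windows):
        raise ValueError("at least one foreground set must be non-empty")
    if not len(bg_windows):
        raise ValueError("background set must be non-empty")
    pat = _as_pattern(pattern)
    all_seqs = list(fg_up_windows) + list(fg_down_windows) + list(bg_windows)
    lengths = {len(s) for s in all_seqs}
    if len(lengths) != 1:
        raise ValueError("all windows must have equal length (3'ss-anchored)")
    seq_len = lengths.pop()
    if window_len > seq_len:
        raise ValueError("sliding window longer than the sequences")

    def hit_starts(seqs: Sequence[str]) -> list[list[int]]:
        return [[h.offset for h in scan_motif(s, pat)] for s in seqs]

    sets = {
        "up": hit_starts(fg_up_windows),
        "down": hit_starts(fg_down_windows),
        "bg": hit_starts(bg_windows),
    }
    plen = len(pat)
    rows = []
    for pos in range(0, seq_len - window_len + 1, step):
        lo, hi = pos, pos + window_len - plen  # full containment
        frac = {}
        npos = {}
        for name, starts in sets.items():
            if not starts:
                frac[name] = np.nan
                npos[name] = 0
                continue
            n_hit = sum(any(lo <= s <= hi for s in st) for st in starts)
            frac[name] = n_hit / len(starts)
            npos[name] = n_hit

        def two_prop_p(name: str) -> float:
            n_fg = len(sets[name])
            if n_fg == 0:
                return np.nan
            a, b = npos[name], n_fg - npos[name]
            c, d = npos["bg"], len(sets["bg"]) - npos["bg"]
            try:
                return chi_squared_2x2(a, b, c, d).p_value
            except ValueError:  # zero margin: identical all-or-none coverage
                return 1.0

        rows.append(
            {
                "position": pos,
                "frac_up": frac["up"],
                "frac_down": frac["down"],
                "frac_bg": frac["bg"],
                "p_up": two_prop_p("up"),
                "p_down": two_prop_p("down"),
            }
        )
    return pd.DataFrame(rows)
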