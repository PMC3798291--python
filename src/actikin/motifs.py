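"""Exact-match scanning of 3'-UTR sequences for cis-regulatory elements.

The element inventory covers the classes commonly annotated on
activity-regulated neuronal 3'-UTRs: AU-rich elements (AUUUA) implicated in
mRNA destabilisation, U-rich motifs (UUUAAA), K-boxes (UGUGAU core, a
conserved miRNA seed-match class), UUGUUGG(G) elements suggested to direct
activity-dependent polyadenylation, and canonical polyadenylation signals
(AAUAAA / AUUAAA).

Counting policy: every distinct start position yields one hit, and hits may
overlap freely within and across classes — an AU-rich stretch like
``AUUUAUUUA`` therefore carries two AREs.  For UUGUUGG(G), the longest match
at a start is taken and counted once.  Sequences are scanned as given
(sense strand); T and U are equivalent and case is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "MotifDef",
    "MotifHit",
    "DEFAULT_MOTIFS",
    "normalize_rna",
    "scan_sequence",
    "scan_records",
    "summarize_motifs",
]

_VALID = frozenset("ACGUN")


@dataclass(frozen=True)
class MotifDef:
    """A motif class: exact RNA patterns, optionally greedily extensible."""

    class_name: str
    patterns: tuple[str, ...]
    greedy_extension: str = ""  # optional single trailing base

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError(f"motif class {self.class_name!r} has no patterns")


DEFAULT_MOTIFS: tuple[MotifDef, ...] = (
    MotifDef("ARE", ("AUUUA",)),
    MotifDef("URM", ("UUUAAA",)),
    MotifDef("KBOX", ("UGUGAU",)),
    MotifDef("UUGUUGG", ("UUGUUGG",), greedy_extension="G"),
    MotifDef("POLYA", ("AAUAAA", "AUUAAA")),
)


@dataclass(frozen=True, order=True)
class MotifHit:
    """One motif occurrence; 0-based half-open coordinates on the given strand."""

    sequence_id: str
    class_name: str
    start: int
    end: int
    matched_text: str


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA T to RNA U; reject illegal characters."""
    norm = seq.upper().replace("T", "U")
    for pos, ch in enumerate(norm):
        if ch not in _VALID:
            raise ValueError(
                f"illegal character {seq[pos]!r} at position {pos}; "
                "expected A/C/G/T/U/N"
            )
    return norm


def scan_sequence(seq, motifs=DEFAULT_MOTIFS, sequence_id: str = "") -> list[MotifHit]:
    """All motif occurrences in one sequence, sorted by (start, class).

    Occurrences at distinct starts are all reported (overlaps allowed); at
    one start a class yields a single hit, the longest matching pattern
    (greedy extension included).  N never matches.
    """
    norm = normalize_rna(str(seq))
    hits: list[MotifHit] = []
    for motif in motifs:
        best_at_start: dict[int, str] = {}
        for pattern in motif.patterns:
            start = norm.find(pattern)
            while start != -1:
                text = pattern
                ext = motif.greedy_extension
                if ext and norm.startswith(pattern + ext, start):
                    text = pattern + ext
                if len(text) > len(best_at_start.get(start, "")):
                    best_at_start[start] = text
                start = norm.find(pattern, start + 1)
        hits.extend(
            MotifHit(sequence_id, motif.class_name, s, s + len(t), t)
            for s, t in best_at_start.items()
        )
    return sorted(hits, key=lambda h: (h.start, h.class_name))


def scan_records(records, motifs=DEFAULT_MOTIFS) -> list[MotifHit]:
    """Scan an iterable of (sequence_id, sequence) pairs."""
    hits: list[MotifHit] = []
    for seq_id, seq in records:
        hits.extend(scan_sequence(seq, motifs, sequence_id=seq_id))
    return hits


def summarize_motifs(
    hits, per_sequence: bool = False, motifs=DEFAULT_MOTIFS
) -> pd.DataFrame:
    """Hit counts per motif class, optionally broken down by sequence.

    All classes of the motif set appear in the table even with zero hits;
    per-sequence counts sum to the global totals by construction.
    """
    classes = [m.class_name for m in motifs]
    df = pd.DataFrame(
        [(h.sequence_id, h.class_name) for h in hits],
        columns=["sequence_id", "class_name"],
    )
    if per_sequence:
        counts = (
            df.groupby(["sequence_id", "class_name"]).size().unstack(fill_value=0)
            if len(df)
            else pd.DataFrame(columns=classes)
        )
        return counts.reindex(columns=classes, fill_value=0)
    counts = df["class_name"].value_counts()
    return pd.DataFrame({"count": [int(counts.get(c, 0)) for c in classes]},
                        index=pd.Index(classes, name="class_name"))
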