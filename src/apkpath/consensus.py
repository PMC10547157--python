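"""Hit-table filtering and consensus-closest representative selection.

The enzyme-mining procedure this supports keeps candidate
phosphoketolase hits whose best match is the target class with identity
strictly above 40% over an alignment strictly longer than 600 residues,
then represents each ortholog group by the member sequence closest to
the group's column-wise majority consensus.  The upstream homology
searches and ortholog clustering are consumed as precomputed tables;
only the bespoke filtering and selection steps are implemented.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

GAP_CHARS = frozenset("-.")

DEFAULT_MIN_IDENTITY = 40.0  # strict: identity must exceed this
DEFAULT_MIN_LENGTH = 600  # strict: alignment length must exceed this


@dataclass(frozen=True)
class HitRecord:
    """One homology-search hit: query, best-hit class, identity, length."""

    query_id: str
    hit_class: str
    identity: float
    align_length: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError(f"{self.query_id}: identity must be in [0, 100]")
        if self.align_length < 0:
            raise ValueError(f"{self.query_id}: align_length must be >= 0")


def filter_hits(
    records: Sequence[HitRecord],
    target_class: str = "XFP",
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> list[HitRecord]:
    """Keep hits of the target class passing both strict thresholds.

    Both bounds are strict ("more than"): identity exactly at
    ``min_identity`` or length exactly at ``min_length`` is dropped.
    Order-preserving and idempotent.
    """
    return [
        r
        for r in records
        if r.hit_class == target_class
        and r.identity > min_identity
        and r.align_length > min_length
    ]


def read_hit_table(path, sep: str = "\t") -> list[HitRecord]:
    """Load a delimited hit table with columns query_id, hit_class, identity, align_length."""
    df = pd.read_csv(path, sep=sep)
    required = {"query_id", "hit_class", "identity", "align_length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    return [
        HitRecord(
            query_id=str(r.query_id),
            hit_class=str(r.hit_class),
            identity=float(r.identity),
            align_length=int(r.align_length),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------
# Consensus and representative selection
# ---------------------------------------------------------------------

AlignmentLike = Union[Sequence[str], Sequence[tuple[str, str]]]


def _normalize(alignment) -> tuple[list[str], list[str]]:
    """Accept plain strings, (id, seq) pairs, SeqRecords or an MSA."""
    ids: list[str] = []
    rows: list[str] = []
    for i, item in enumerate(alignment):
        if isinstance(item, str):
            ids.append(f"row{i}")
            rows.append(item)
        elif isinstance(item, tuple) and len(item) == 2:
            ids.append(str(item[0]))
            rows.append(str(item[1]))
        else:  # SeqRecord-ish
            ids.append(getattr(item, "id", f"row{i}"))
            rows.append(str(getattr(item, "seq", item)))
    if not rows:
        raise ValueError("empty alignment")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("ragged alignment: rows differ in length")
    return ids, [r.upper() for r in rows]


def consensus_of(alignment) -> str:
    """Column-wise majority consensus of an alignment.

    Gaps are excluded from the tally unless a column is entirely gaps
    (then the consensus keeps a gap).  A tied column resolves to the
    alphabetically first of the tied residues, a deterministic rule the
    mining procedure itself leaves open.
    """
    _, rows = _normalize(alignment)
    width = len(rows[0])
    out = []
    for col in range(width):
        counts = Counter(
            r[col] for r in rows if r[col] not in GAP_CHARS
        )
        if not counts:
            out.append("-")
            continue
        best = max(counts.values())
        out.append(min(ch for ch, n in counts.items() if n == best))
    return "".join(out)


@dataclass(frozen=True)
class ConsensusResult:
    """Consensus sequence plus the chosen representative and score table."""

    consensus: str
    representative_id: str
    representative_index: int
    scores: tuple[float, ...]  # per input sequence, higher is closer
    distances: tuple[int, ...]  # consensus columns at which each row differs
    tie: bool
    metric: str


def closest_to_consensus(alignment, metric: str = "column_match") -> ConsensusResult:
    """Pick the member sequence closest to the family consensus.

    ``metric="column_match"`` (default) scores each row by the count of
    columns where it matches the consensus residue, gap positions
    excluded.  ``metric="identity"`` instead uses the fraction of
    mutually non-gap columns that match, an alternative reading of
    "closest".  Ties resolve to the earliest input row and are flagged.
    """
    ids, rows = _normalize(alignment)
    cons = consensus_of(alignment)
    scores: list[float] = []
    distances: list[int] = []
    for row in rows:
        matches = 0
        both_nongap = 0
        diff = 0
        for a, c in zip(row, cons):
            if c in GAP_CHARS:
                continue
            if a in GAP_CHARS:
                diff += 1
                continue
            both_nongap += 1
            if a == c:
                matches += 1
            else:
                diff += 1
        distances.append(diff)
        if metric == "column_match":
            scores.append(float(matches))
        elif metric == "identity":
            scores.append(matches / both_nongap if both_nongap else 0.0)
        else:
            raise ValueError(f"unknown metric {metric!r}")
    best = max(scores)
    winners = [i for i, sc in enumerate(scores) if sc == best]
    rep = winners[0]
    return ConsensusResult(
        consensus=cons,
        representative_id=ids[rep],
        representative_index=rep,
        scores=tuple(scores),
        distances=tuple(distances),
        tie=len(winners) > 1,
        metric=metric,
    )


def load_alignment_fasta(path) -> list[tuple[str, str]]:
    """Aligned FASTA -> list of (id, sequence) pairs."""
    from Bio import SeqIO

    pairs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]
    if not pairs:
        raise ValueError(f"no sequences in {path}")
    return pairs
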