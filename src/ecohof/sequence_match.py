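"""Query-to-reference match records and the hit criteria for trait transfer.

Match records are the standard 12-column tabular alignment format
(qseqid sseqid pident length mismatch gapopen qstart qend sstart send
evalue bitscore). A query "hit" is a match with >= 97% identity and e-value
<= 0.001 (both bounds inclusive); per query the best hit is kept by bitscore,
breaking ties by e-value and then subject id.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MatchHit",
    "read_match_table",
    "write_match_table",
    "apply_hit_criteria",
    "percent_hits",
    "rank_bin_match_rates",
]

MIN_IDENTITY = 97.0
MAX_EVALUE = 0.001


@dataclass(frozen=True)
class MatchHit:
    """One query-to-reference alignment record (12-column tabular row)."""

    query_id: str
    subject_id: str
    pct_identity: float
    align_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity out of [0, 100]: {self.pct_identity}")
        if self.evalue < 0:
            raise ValueError(f"negative e-value: {self.evalue}")


def read_match_table(path: str | Path) -> list[MatchHit]:
    """Parse a 12-column tabular match file; malformed rows raise with line number."""
    hits: list[MatchHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(f"{path}: line {lineno}: expected 12 columns, got {len(fields)}")
            try:
                hits.append(
                    MatchHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pct_identity=float(fields[2]),
                        align_len=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        q_start=int(fields[6]),
                        q_end=int(fields[7]),
                        s_start=int(fields[8]),
                        s_end=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return hits


def write_match_table(hits: Iterable[MatchHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id, h.subject_id, h.pct_identity, h.align_len,
                        h.mismatches, h.gap_opens, h.q_start, h.q_end,
                        h.s_start, h.s_end, h.evalue, h.bitscore,
                    )
                )
                + "\n"
            )


def apply_hit_criteria(
    hits: Iterable[MatchHit],
    min_identity: float = MIN_IDENTITY,
    max_evalue: float = MAX_EVALUE,
) -> dict[str, MatchHit]:
    """Best qualifying hit per query.

    Filters to pct_identity >= min_identity and evalue <= max_evalue (both
    inclusive), then keeps per query the hit with maximal bitscore, breaking
    ties by minimal e-value and then lexicographic subject id — deterministic
    under any permutation of the input rows.
    """
    best: dict[str, MatchHit] = {}
    for h in hits:
        if h.pct_identity < min_identity or h.evalue > max_evalue:
            continue
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        key_new = (-h.bitscore, h.evalue, h.subject_id)
        key_cur = (-cur.bitscore, cur.evalue, cur.subject_id)
        if key_new < key_cur:
            best[h.query_id] = h
    return best


def percent_hits(query_ids: Sequence[str], best_hits: Mapping[str, MatchHit]) -> float:
    """Percentage of queries with a qualifying best hit."""
    if len(query_ids) == 0:
        raise ValueError("no query ids")
    n_hit = sum(1 for q in query_ids if q in best_hits)
    return 100.0 * n_hit / len(query_ids)


def rank_bin_match_rates(
    query_abundances: Mapping[str, float] | pd.Series,
    best_hits: Mapping[str, MatchHit],
    n_bins: int = 1000,
) -> pd.DataFrame:
    """Match proportion per abundance-rank bin.

    Queries are sorted by decreasing total abundance (ties broken by
    lexicographic id) and split into ``n_bins`` contiguous near-equal bins,
    earlier bins taking the remainder; bin 1 holds the most abundant taxa.

    Returns a DataFrame with columns ``bin`` (1-based), ``n_otus`` and
    ``prop_matched``.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    ab = pd.Series(dict(query_abundances)) if not isinstance(query_abundances, pd.Series) else query_abundances
    n = len(ab)
    if n < n_bins:
        raise ValueError(
            f"only {n} query OTUs for {n_bins} bins; use n_bins <= {n}"
        )
    order = sorted(ab.index, key=lambda q: (-ab[q], q))
    matched = np.array([q in best_hits for q in order], dtype=float)
    chunks = np.array_split(matched, n_bins)
    return pd.DataFrame(
        {
            "bin": np.arange(1, n_bins + 1),
            "n_otus": [len(c) for c in chunks],
            "prop_matched": [float(c.mean()) for c in chunks],
        }
    )
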