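"""Assign a query protein to candidate gene (sub)trees.

The query is scored against the representative ("profile") sequences with
Smith-Waterman local alignment (BLOSUM62, gap open 11 / extend 1) and
BLAST-style statistics: bit score S' = (lambda*S - ln K)/ln 2 with the
standard gapped constants lambda = 0.267, K = 0.041, and e-value
E = m*n*2^(-S') where m is the query length and n the total residue count
of the profile database.  Hits below the e-value cutoff vote for their
(family, subtree); any other tree whose best hit is within a factor of
``ambiguity_ratio`` (10^10) of the best e-value is kept as an additional
candidate.  If the first pass finds nothing, a sensitive retry disables the
shared-4-mer pre-filter so every representative is fully aligned.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner, substitution_matrices

from .treeio import InputError, SEQ_ALPHABET

KA_LAMBDA = 0.267  # gapped BLOSUM62, 11/1
KA_K = 0.041
_WORD_SIZE = 4
_MIN_QUERY_LEN = 10


@dataclass(frozen=True)
class SearchConfig:
    """Profile-search parameters (defaults match the deployed tool)."""

    evalue_cutoff: float = 1e-3
    ambiguity_ratio: float = 1e10
    engine: str = "builtin"
    sensitive_retry: bool = True
    max_candidates: int = 5

    def __post_init__(self):
        if self.evalue_cutoff <= 0:
            raise InputError("evalue_cutoff must be > 0")
        if self.ambiguity_ratio < 1:
            raise InputError("ambiguity_ratio must be >= 1")
        if self.engine not in ("builtin", "external"):
            raise InputError(f"unknown search engine {self.engine!r}")


@dataclass(frozen=True)
class SearchHit:
    rep_id: str
    family_id: str
    subtree_id: str
    evalue: float
    bitscore: float
    raw_score: float = 0.0

    @property
    def sort_key(self):
        return (self.evalue, -self.bitscore, self.rep_id)


@dataclass
class AssignResult:
    """Candidate trees for one query, with per-candidate best hits."""

    candidates: list[tuple[str, str]]  # (family, subtree), ordered by best e-value
    best_hits: dict[tuple[str, str], SearchHit] = field(default_factory=dict)
    sensitive_pass: bool = False

    def __bool__(self) -> bool:
        return bool(self.candidates)


def _aligner() -> PairwiseAligner:
    aln = PairwiseAligner()
    aln.mode = "local"
    aln.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aln.open_gap_score = -11.0
    aln.extend_gap_score = -1.0
    return aln


def validate_query(query: str) -> str:
    query = query.strip().upper()
    if not query:
        raise InputError("empty query sequence")
    bad = set(query) - SEQ_ALPHABET
    if bad:
        raise InputError(
            f"query contains non-amino-acid character(s): {sorted(bad)}"
        )
    if len(query) < _MIN_QUERY_LEN:
        raise InputError(
            f"query too short ({len(query)} residues; minimum {_MIN_QUERY_LEN})"
        )
    return query


def bit_score(raw: float) -> float:
    return (KA_LAMBDA * raw - math.log(KA_K)) / math.log(2.0)


def evalue(raw: float, query_len: int, db_residues: int) -> float:
    return query_len * db_residues * 2.0 ** (-bit_score(raw))


def _kmers(seq: str, k: int = _WORD_SIZE) -> set[str]:
    return {seq[i: i + k] for i in range(len(seq) - k + 1)}


def builtin_search(
    query: str,
    representatives: Mapping[str, str],
    resolver: Mapping[str, tuple[str, str]] | None = None,
    sensitive: bool = False,
) -> list[SearchHit]:
    """Smith-Waterman search of a query against the representative set.

    At default sensitivity a representative is only aligned if it shares at
    least one exact 4-mer with the query (a stand-in for a fast seeded first
    pass); the sensitive pass aligns everything.  Hits are sorted by
    ascending e-value, then descending bit score, then id.
    """
    query = validate_query(query)
    if not representatives:
        raise InputError("empty representative set")
    db_residues = sum(len(s) for s in representatives.values())
    aligner = _aligner()
    query_words = _kmers(query)
    hits: list[SearchHit] = []
    for rid in representatives:
        seq = representatives[rid].upper()
        if not sensitive and not (query_words & _kmers(seq)):
            continue
        raw = aligner.score(query, seq)
        fam, sid = resolver[rid] if resolver is not None else ("", "")
        hits.append(
            SearchHit(
                rep_id=rid,
                family_id=fam,
                subtree_id=sid,
                evalue=evalue(raw, len(query), db_residues),
                bitscore=bit_score(raw),
                raw_score=raw,
            )
        )
    hits.sort(key=lambda h: h.sort_key)
    return hits


def assign_trees(hits: list[SearchHit], cfg: SearchConfig) -> list[tuple[str, str]]:
    """Reduce sorted hits to an ordered list of candidate (family, subtree).

    Hits above the e-value cutoff are dropped.  The best remaining hit fixes
    the primary candidate; the best hit of every other tree is kept as well
    when its e-value is < best_e * ambiguity_ratio.  An e-value of exactly 0
    (bit-score underflow) uses the smallest positive float as the base of
    the ratio test.
    """
    passing = [h for h in hits if h.evalue <= cfg.evalue_cutoff]
    if not passing:
        return []
    best_per_tree: dict[tuple[str, str], SearchHit] = {}
    for h in passing:  # already sorted: first seen per tree is its best
        key = (h.family_id, h.subtree_id)
        if key not in best_per_tree:
            best_per_tree[key] = h
    ordered = sorted(best_per_tree.values(), key=lambda h: h.sort_key)
    best_e = ordered[0].evalue
    base = best_e if best_e > 0 else math.ulp(0.0)
    threshold = base * cfg.ambiguity_ratio
    out = [(ordered[0].family_id, ordered[0].subtree_id)]
    for h in ordered[1:]:
        if h.evalue < threshold:
            out.append((h.family_id, h.subtree_id))
    return out[: cfg.max_candidates]


def search_with_retry(query: str, db, cfg: SearchConfig | None = None) -> AssignResult:
    """One (or, if empty, two) profile-search passes against a built database.

    The second pass runs only when ``cfg.sensitive_retry`` is set and the
    default-sensitivity pass assigned no tree.
    """
    cfg = cfg or SearchConfig()
    if cfg.engine != "builtin":
        raise InputError(
            "external search engines must be invoked through their adapter; "
            "only the builtin engine is available here"
        )
    rep_seqs, rep_where = db.representative_index()
    hits = builtin_search(query, rep_seqs, rep_where, sensitive=False)
    candidates = assign_trees(hits, cfg)
    sensitive = False
    if not candidates and cfg.sensitive_retry:
        hits = builtin_search(query, rep_seqs, rep_where, sensitive=True)
        candidates = assign_trees(hits, cfg)
        sensitive = bool(candidates)
    wanted = set(candidates)
    best_hits: dict[tuple[str, str], SearchHit] = {}
    for h in hits:
        key = (h.family_id, h.subtree_id)
        if key in wanted and key not in best_hits:
            best_hits[key] = h
    return AssignResult(candidates=candidates, best_hits=best_hits, sensitive_pass=sensitive)
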