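"""End-to-end search pipeline and BLAST-tabular reporting."""

from __future__ import annotations

import logging
import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

from .alphabet import SubstitutionMatrix, load_matrix, normalize_sequence
from .index import ProteinDatabase, SuffixIndex
from .masking import DEFAULT_HICUT, DEFAULT_LOCUT, DEFAULT_WINDOW, seg_mask
from .sans import DEFAULT_MIN_SUFFIX, asymmetric_sans, top_candidates
from .stats import AlignmentHit, KarlinAltschulParams, rank_hits

logger = logging.getLogger("topaz")


@dataclass(frozen=True)
class SearchConfig:
    """Search parameters; defaults are the engine's standard mode."""

    seeds: int = 300_000          # global vote budget V per query
    alignments: int = 5_000       # candidates N passed to verification
    max_hits: int = 1_000         # H hits reported per query
    evalue_max: float = 1.0
    threads: int = 1
    min_suffix: int = DEFAULT_MIN_SUFFIX
    seg: bool = True
    seg_window: int = DEFAULT_WINDOW
    seg_locut: float = DEFAULT_LOCUT
    seg_hicut: float = DEFAULT_HICUT
    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self):
        if self.seeds < 0:
            raise ValueError("seeds must be >= 0")
        if self.alignments < 1:
            raise ValueError("alignments must be >= 1")
        if self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")


#: The speed-over-sensitivity preset.
FAST_PRESET = {"seeds": 100_000, "alignments": 1_500}


def search_one(
    query_id: str,
    query_seq: str,
    index: SuffixIndex,
    matrix: SubstitutionMatrix,
    config: SearchConfig,
    params: KarlinAltschulParams,
) -> list[AlignmentHit]:
    """Retrieve, verify and rank hits for a single query sequence."""
    seq = normalize_sequence(query_seq)
    q_codes = index.ordering.encode(seq)
    mask = (
        seg_mask(seq, config.seg_window, config.seg_locut, config.seg_hicut)
        if config.seg
        else None
    )
    vt = asymmetric_sans(
        index, matrix, q_codes, config.seeds, q_mask=mask,
        min_suffix=config.min_suffix,
    )
    candidates = top_candidates(vt, config.alignments) if vt.budget_used else []
    hits = rank_hits(
        candidates, query_id, seq, index, matrix, params,
        H=config.max_hits, evalue_max=config.evalue_max,
    )
    logger.debug(
        "query %s: %d votes spent, %d candidates, %d hits",
        query_id, vt.budget_used, len(candidates), len(hits),
    )
    return hits


def search_database(
    index: SuffixIndex,
    queries: ProteinDatabase,
    config: SearchConfig | None = None,
) -> list[tuple[str, list[AlignmentHit]]]:
    """Search every query against the index, in query input order.

    Parallelism is across queries only, so output is identical for any
    thread count.
    """
    config = config or SearchConfig()
    matrix = load_matrix(config.matrix)
    if matrix.name != index.matrix_name:
        warnings.warn(
            f"index was built for matrix {index.matrix_name!r}; "
            f"searching with {matrix.name!r}",
            stacklevel=2,
        )
    db_residues = int(len(index.text)) - index.n_proteins  # delimiters excluded
    params = KarlinAltschulParams(
        gap_open=config.gap_open,
        gap_extend=config.gap_extend,
        db_residues=db_residues,
    )

    def run(rec):
        return rec.id, search_one(rec.id, rec.sequence, index, matrix, config, params)

    if config.threads > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            return list(pool.map(run, queries.records))
    return [run(rec) for rec in queries.records]


def _format_evalue(e: float) -> str:
    if e == 0.0:
        return "0.0"
    return f"{e:.2g}"


def write_tabular(hits: list[AlignmentHit], stream) -> int:
    """Write hits as 12-column BLAST tabular (outfmt 6) rows; returns the
    number of rows written."""
    n = 0
    for h in hits:
        r = h.result
        row = (
            h.query_id,
            h.subject_id,
            f"{r.percent_identity:.2f}",
            str(r.aligned_length),
            str(r.mismatches),
            str(r.gap_openings),
            str(r.q_start),
            str(r.q_end),
            str(r.s_start),
            str(r.s_end),
            _format_evalue(h.evalue),
            f"{h.bitscore:.1f}",
        )
        stream.write("\t".join(row) + "\n")
        n += 1
    return n
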