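"""Position-weight-matrix scanning with the relative profile score.

A position frequency matrix (PFM, JASPAR-style base counts per motif
column) is converted to a log-odds position weight matrix; windows of
a promoter sequence are then scored and kept when their *relative*
score,

    (raw - min_possible) / (max_possible - min_possible),

reaches a threshold (0.99 by default, the level used for stringent
promoter scans).  Hits found on a degapped alignment row can be mapped
back to alignment columns and intersected with a deletion event to
decide whether the binding site was lost.

Coordinates are 1-based inclusive on the + strand of the scanned
sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .promoter_evolution import IndelEvent

BASE_ORDER = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifModel:
    """A PFM together with its derived log-odds matrix and score range."""

    name: str
    counts: np.ndarray  # (4, k), rows A,C,G,T
    background: np.ndarray  # (4,)
    pseudocount: float
    log_odds: np.ndarray  # (4, k)
    col_min: np.ndarray  # (k,)
    col_max: np.ndarray  # (k,)

    @property
    def k(self) -> int:
        return self.counts.shape[1]

    @property
    def min_score(self) -> float:
        return float(self.col_min.sum())

    @property
    def max_score(self) -> float:
        return float(self.col_max.sum())

    @property
    def consensus(self) -> str:
        return "".join(BASE_ORDER[i] for i in self.log_odds.argmax(axis=0))


def pwm_from_counts(
    counts,
    name: str = "",
    pseudocount: float = 0.8,
    background: Sequence[float] | None = None,
) -> MotifModel:
    """Build a scannable motif model from a 4 x k count matrix.

    Frequencies are ``(count + pseudocount*background) / (colsum +
    pseudocount)`` and log-odds are log2(frequency / background).  The
    default background is uniform and the default pseudocount 0.8,
    distributed according to the background.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
        raise ValueError("counts must be a 4 x k matrix with k >= 1")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    bg = (
        np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    )
    if bg.shape != (4,) or np.any(bg <= 0) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be 4 positive probabilities summing to 1")
    col_sums = counts.sum(axis=0)
    if pseudocount == 0 and np.any(col_sums == 0):
        raise ValueError("zero-sum column needs a positive pseudocount")
    freq = (counts + pseudocount * bg[:, None]) / (col_sums + pseudocount)
    log_odds = np.log2(freq / bg[:, None])
    return MotifModel(
        name=name,
        counts=counts,
        background=bg,
        pseudocount=float(pseudocount),
        log_odds=log_odds,
        col_min=log_odds.min(axis=0),
        col_max=log_odds.max(axis=0),
    )


def raw_score(model: MotifModel, word: str) -> float:
    word = word.upper()
    if len(word) != model.k:
        raise ValueError(f"word length {len(word)} != motif width {model.k}")
    try:
        idx = [_BASE_INDEX[b] for b in word]
    except KeyError as exc:
        raise ValueError(f"word contains non-ACGT symbol {exc}") from None
    return float(model.log_odds[idx, range(model.k)].sum())


def relative_score(model: MotifModel, word: str) -> float:
    """Score of a k-mer rescaled to [0, 1] between the worst and best
    possible words under the model."""
    rng = model.max_score - model.min_score
    if rng == 0:
        return 1.0  # uninformative matrix: every word is equally "best"
    return (raw_score(model, word) - model.min_score) / rng


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    start: int  # 1-based inclusive, + strand coordinates
    end: int
    strand: str  # "+" or "-"
    word: str  # matched word, as read on the scanned strand
    raw: float
    relative: float


def scan(
    seq: str,
    model: MotifModel,
    threshold: float = 0.99,
    both_strands: bool = True,
    seq_id: str = "",
) -> list[MotifHit]:
    """All windows whose relative score reaches the threshold.

    The input must be gapless (degap aligned rows first, keeping a
    column map).  Reverse-strand hits are scored on the reverse
    complement but reported with + strand window coordinates and
    strand "-".  Windows containing non-ACGT symbols (e.g. N) never
    score and are silently skipped.
    """
    seq = seq.upper()
    if "-" in seq:
        raise ValueError("scan needs a gapless sequence; degap first")
    k = model.k
    hits: list[MotifHit] = []
    strands = ["+", "-"] if both_strands else ["+"]
    for start in range(len(seq) - k + 1):
        window = seq[start : start + k]
        if any(b not in _BASE_INDEX for b in window):
            continue
        for strand in strands:
            word = window if strand == "+" else revcomp(window)
            rel = relative_score(model, word)
            if rel >= threshold:
                hits.append(
                    MotifHit(
                        seq_id=seq_id,
                        start=start + 1,
                        end=start + k,
                        strand=strand,
                        word=word,
                        raw=raw_score(model, word),
                        relative=rel,
                    )
                )
    return hits


# ---------------------------------------------------------------------------
# alignment mapping and deletion overlap


def degap_with_map(aligned_row: str) -> tuple[str, list[int]]:
    """Remove gaps from an aligned row, returning the gapless sequence
    and, per gapless position, its 1-based alignment column."""
    seq = []
    colmap = []
    for col, sym in enumerate(aligned_row.upper(), start=1):
        if sym != "-":
            seq.append(sym)
            colmap.append(col)
    return "".join(seq), colmap


@dataclass(frozen=True)
class AlignedHit:
    hit: MotifHit
    start_col: int  # 1-based alignment columns
    end_col: int


def map_hits_to_alignment(
    hits: Iterable[MotifHit], colmap: Sequence[int]
) -> list[AlignedHit]:
    out = []
    for hit in hits:
        if hit.end > len(colmap):
            raise ValueError(
                f"hit [{hit.start},{hit.end}] extends past the {len(colmap)}-column map"
            )
        out.append(AlignedHit(hit, colmap[hit.start - 1], colmap[hit.end - 1]))
    return out


def deletion_overlap(
    aligned_hits: Sequence[AlignedHit], event: IndelEvent
) -> list[str]:
    """Per-hit fate under a deletion: ``lost`` when the hit interval
    lies fully inside the deleted columns, ``truncated`` when it
    partially overlaps, ``unaffected`` otherwise."""
    del_start, del_end = event.start, event.start + event.length - 1
    statuses = []
    for ah in aligned_hits:
        if ah.start_col >= del_start and ah.end_col <= del_end:
            statuses.append("lost")
        elif ah.end_col < del_start or ah.start_col > del_end:
            statuses.append("unaffected")
        else:
            statuses.append("truncated")
    return statuses


# ---------------------------------------------------------------------------
# JASPAR PFM parsing


def parse_jaspar(path) -> list[MotifModel]:
    """Parse a JASPAR-style PFM text file into motif models.

    Accepts both the bracketed dialect (``A [ 4 19 0 ]``) and bare
    whitespace-separated rows, with rows either labelled A/C/G/T or
    given unlabelled in A,C,G,T order under each ``>ID name`` header.
    """
    models = []
    name = None
    rows: dict[str, list[float]] = {}
    order: list[str] = []

    def flush() -> None:
        nonlocal rows, order
        if name is None and not rows:
            return
        if not rows:
            raise ValueError(f"motif {name!r} has no count rows")
        if set(rows) == set(BASE_ORDER):
            counts = [rows[b] for b in BASE_ORDER]
        elif len(rows) == 4:
            counts = [rows[k] for k in order]
        else:
            raise ValueError(f"motif {name!r} needs 4 count rows, got {len(rows)}")
        models.append(pwm_from_counts(np.array(counts), name=name or ""))
        rows, order = {}, []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].strip()
                continue
            m = re.match(r"^([ACGT])\s*[\[|]?\s*([-\d.eE+\s]+?)\s*\]?$", line)
            if m:
                key, nums = m.group(1), m.group(2)
            else:
                key, nums = f"row{len(rows)}", line.strip("[] ")
            values = [float(x) for x in nums.split()]
            rows[key] = values
            order.append(key)
    flush()
    if not models:
        raise ValueError(f"no motifs found in {path}")
    return models


def hits_to_tsv(hits: Iterable[MotifHit], path, motif_name: str = "") -> None:
    """Write hits as a BED-like TSV (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("seqid\tstart\tend\tmotif\trelative_score\tstrand\n")
        for h in hits:
            fh.write(
                f"{h.seq_id}\t{h.start}\t{h.end}\t{motif_name}\t{h.relative:.4f}\t{h.strand}\n"
            )
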