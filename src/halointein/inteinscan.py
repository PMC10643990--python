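"""PSSM-based detection of inteins and LAGLIDADG HEN blocks in proteomes.

A position-specific scoring matrix (PSSM) is built from an ungapped-core
block alignment with mass-proportional pseudocounts::

    s(p, aa) = log2( (c(p, aa) + alpha * b(aa)) / ((n_p + alpha) * b(aa)) )

where ``c`` are observed counts, ``n_p`` the ungapped count in column p,
``b`` the background distribution (uniform 1/20 by default) and ``alpha``
the pseudocount mass. Window scores are sums over positions; ambiguity
codes (X etc.) score 0.

Detection proceeds in three stages, mirroring how multi-intein genes are
surveyed: (1) scan each protein with a set of intein PSSMs and collect
windows above threshold; (2) merge nearby hits (default within 150
residues — inteins are large) into candidate intein regions and count them
per gene; (3) re-scan each region with the four conserved LAGLIDADG homing
endonuclease (HEN) block PSSMs — a region with at least one HEN block is a
*full* intein, otherwise a *mini*-intein. Group summaries report, per taxon
group, multi- and single-intein gene counts and the percentage of their
inteins that carry a detectable HEN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .flanks import AMINO_ACIDS, _AA_INDEX

logger = logging.getLogger(__name__)

__all__ = [
    "PSSM",
    "ScanHit",
    "InteinCall",
    "build_pssm",
    "scan_sequence",
    "call_inteins",
    "classify_hen",
    "scan_proteome",
    "group_summary",
    "read_fasta",
]

UNIFORM_BACKGROUND = {aa: 1.0 / 20 for aa in AMINO_ACIDS}


@dataclass
class PSSM:
    """Log-odds scores (bits) for an L-column motif.

    ``matrix`` is L x 21: columns 0..19 follow ``AMINO_ACIDS``, column 20 is
    the neutral score (0) given to ambiguity codes.
    """

    name: str
    matrix: np.ndarray = field(repr=False)
    alpha: float = 1.0
    background: dict[str, float] = field(default_factory=lambda: dict(UNIFORM_BACKGROUND), repr=False)

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus_score(self) -> float:
        """Maximum attainable window score (sum of per-column maxima)."""
        return float(self.matrix[:, :20].max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[j] for j in self.matrix[:, :20].argmax(axis=1))

    def default_threshold(self, fraction: float = 0.6) -> float:
        return fraction * self.consensus_score


@dataclass
class ScanHit:
    """One above-threshold window of one PSSM on one sequence."""

    seq_id: str
    offset: int  # 0-based
    score: float  # bits
    pssm: str
    length: int

    @property
    def end(self) -> int:
        return self.offset + self.length


@dataclass
class InteinCall:
    """A merged intein region on one sequence, optionally HEN-classified."""

    seq_id: str
    index: int
    start: int
    end: int
    n_hits: int
    category: str | None = None  # "full" | "mini"
    hen_blocks: list[str] = field(default_factory=list)


def build_pssm(
    block: list[str],
    name: str = "pssm",
    background: dict[str, float] | None = None,
    alpha: float = 1.0,
) -> PSSM:
    """Build a PSSM from an aligned block (equal-length rows, gaps allowed).

    Columns with gaps use only their ungapped counts (per-column ``n_p``).
    """
    if len(block) < 2:
        raise ValueError("a PSSM block needs at least 2 sequences")
    if alpha <= 0:
        raise ValueError("pseudocount mass alpha must be positive")
    lengths = {len(s) for s in block}
    if len(lengths) != 1:
        raise ValueError("block rows have unequal lengths")
    (L,) = lengths
    if L < 1:
        raise ValueError("empty block")
    bg = dict(background or UNIFORM_BACKGROUND)
    bvec = np.array([bg[aa] for aa in AMINO_ACIDS])
    if np.any(bvec <= 0) or not np.isclose(bvec.sum(), 1.0):
        raise ValueError("background must be positive and sum to 1")
    counts = np.zeros((L, 20))
    for row in block:
        for p, res in enumerate(row.upper()):
            j = _AA_INDEX.get(res)
            if j is not None:
                counts[p, j] += 1
    n_p = counts.sum(axis=1, keepdims=True)
    scores = np.log2((counts + alpha * bvec) / ((n_p + alpha) * bvec))
    matrix = np.zeros((L, 21))
    matrix[:, :20] = scores
    return PSSM(name=name, matrix=matrix, alpha=alpha, background=bg)


def _encode(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(c, 20) for c in seq.upper()], dtype=np.intp)


def _window_scores(pssm: PSSM, seq: str) -> np.ndarray:
    """Score of every window offset; empty array if the sequence is short."""
    enc = _encode(seq)
    L = pssm.length
    n = len(enc) - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for p in range(L):
        scores += pssm.matrix[p, enc[p : p + n]]
    return scores


def scan_sequence(
    pssm: PSSM, seq: str, seq_id: str = "seq", threshold: float | None = None
) -> list[ScanHit]:
    """All windows scoring >= threshold, overlapping windows merged.

    ``threshold`` defaults to 60% of the PSSM's consensus score. Runs of
    mutually overlapping above-threshold windows collapse to the single
    best-scoring offset. Hits are sorted by offset.
    """
    if threshold is None:
        threshold = pssm.default_threshold()
    scores = _window_scores(pssm, seq)
    if scores.size == 0:
        logger.warning("scan_sequence(%s): %r shorter than PSSM (%d)", pssm.name, seq_id, pssm.length)
        return []
    above = np.flatnonzero(scores >= threshold)
    hits: list[ScanHit] = []
    i = 0
    while i < len(above):
        j = i
        while j + 1 < len(above) and above[j + 1] < above[i] + pssm.length:
            # extend the run while windows overlap the best-so-far cluster
            j += 1
        run = above[i : j + 1]
        best = run[np.argmax(scores[run])]
        hits.append(
            ScanHit(seq_id=seq_id, offset=int(best), score=float(scores[best]),
                    pssm=pssm.name, length=pssm.length)
        )
        i = j + 1
    return hits


def call_inteins(hits: list[ScanHit], merge_gap: int = 150) -> list[InteinCall]:
    """Collapse hits (any PSSM, one sequence's worth per call set) into regions.

    Hits whose spans are within ``merge_gap`` residues of each other merge
    into one intein region; calls are indexed along the sequence.
    """
    by_seq: dict[str, list[ScanHit]] = {}
    for h in hits:
        by_seq.setdefault(h.seq_id, []).append(h)
    calls: list[InteinCall] = []
    for sid in by_seq:
        hs = sorted(by_seq[sid], key=lambda h: h.offset)
        current: list[ScanHit] = []
        regions: list[list[ScanHit]] = []
        for h in hs:
            if current and h.offset - max(x.end for x in current) > merge_gap:
                regions.append(current)
                current = []
            current.append(h)
        if current:
            regions.append(current)
        for k, reg in enumerate(regions):
            calls.append(
                InteinCall(
                    seq_id=sid,
                    index=k,
                    start=min(h.offset for h in reg),
                    end=max(h.end for h in reg),
                    n_hits=len(reg),
                )
            )
    return calls


def classify_hen(
    call: InteinCall,
    seq: str,
    hen_pssms: list[PSSM],
    threshold: float | None = None,
    margin: int = 50,
) -> InteinCall:
    """Categorize a called intein as full (HEN present) or mini.

    The region (plus ``margin`` residues each side) is scanned with each HEN
    block PSSM; the call is *full* iff at least one block scores at or above
    threshold (default: each PSSM's 60%-of-consensus threshold).
    """
    lo = max(0, call.start - margin)
    hi = min(len(seq), call.end + margin)
    region = seq[lo:hi]
    detected = []
    for p in hen_pssms:
        th = threshold if threshold is not None else p.default_threshold()
        if scan_sequence(p, region, seq_id=call.seq_id, threshold=th):
            detected.append(p.name)
    call.hen_blocks = detected
    call.category = "full" if detected else "mini"
    return call


def scan_proteome(
    proteome: dict[str, str],
    intein_pssms: list[PSSM],
    hen_pssms: list[PSSM] | None = None,
    threshold: float | None = None,
    merge_gap: int = 150,
) -> list[InteinCall]:
    """Scan every protein with the intein PSSM set and classify the calls."""
    all_hits: list[ScanHit] = []
    for sid, seq in proteome.items():
        for p in intein_pssms:
            all_hits.extend(scan_sequence(p, seq, seq_id=sid, threshold=threshold))
    calls = call_inteins(all_hits, merge_gap=merge_gap)
    if hen_pssms:
        for c in calls:
            classify_hen(c, proteome[c.seq_id], hen_pssms)
    return sorted(calls, key=lambda c: (c.seq_id, c.index))


def group_summary(
    calls: list[InteinCall], groups: dict[str, str], all_genes: list[str] | None = None
) -> pd.DataFrame:
    """Per-group multi/single intein gene counts and %-with-HEN.

    ``groups`` maps sequence/gene id -> group label. Percentage denominators
    are intein counts (not gene counts); groups without the relevant genes
    report NaN percentages. ``all_genes`` may list genes with zero calls so
    empty groups still appear.
    """
    missing = [c.seq_id for c in calls if c.seq_id not in groups]
    if missing:
        raise ValueError(f"calls without a group label: {sorted(set(missing))[:5]}")
    per_gene: dict[str, list[InteinCall]] = {}
    for c in calls:
        per_gene.setdefault(c.seq_id, []).append(c)
    rows = {}
    group_names = sorted(set(groups[g] for g in (all_genes or groups)))
    for g in group_names:
        rows[g] = {
            "multi_intein_genes": 0,
            "multi_inteins": 0,
            "multi_inteins_full": 0,
            "single_intein_genes": 0,
            "single_inteins_full": 0,
        }
    for gene, cs in per_gene.items():
        r = rows[groups[gene]]
        n_full = sum(1 for c in cs if c.category == "full")
        if len(cs) >= 2:
            r["multi_intein_genes"] += 1
            r["multi_inteins"] += len(cs)
            r["multi_inteins_full"] += n_full
        else:
            r["single_intein_genes"] += 1
            r["single_inteins_full"] += n_full
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "group"
    with np.errstate(divide="ignore", invalid="ignore"):
        out["pct_multi_with_hen"] = np.where(
            out["multi_inteins"] > 0,
            100.0 * out["multi_inteins_full"] / out["multi_inteins"],
            np.nan,
        )
        out["pct_single_with_hen"] = np.where(
            out["single_intein_genes"] > 0,
            100.0 * out["single_inteins_full"] / out["single_intein_genes"],
            np.nan,
        )
    return out


def read_fasta(path: str) -> dict[str, str]:
    """Read a protein FASTA into an id -> sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
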