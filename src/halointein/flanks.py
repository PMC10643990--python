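"""Insertion-site flank extraction and composition summaries.

Intein insertion points are between-residue coordinates on a protein
alignment: an annotated site occupies alignment columns ``[start, end)``
(the intein block), the −1 residue is the last ungapped residue before
``start`` and the +1 residue the first ungapped residue at or after ``end``.
A sequence counts as *invaded* at a site when at least half of the block's
columns are ungapped (configurable), which is robust to ragged block ends.

Flank windows collect up to ``w`` ungapped *residues* per side (gaps are
skipped, so the window is measured in residues, not alignment columns).
Per-column information content uses the standard small-sample correction
``e_n = 19 / (2 ln2 n)`` and clamps negative corrected values at zero.

The biological signal this module quantifies: inteins integrate between a
−1/+1 residue pair, and successful protein splicing needs a nucleophile
(S/C/T) at +1 — a proline there blocks splicing, which is why invaded and
uninvaded copies of a site can show a sharp S-versus-P dichotomy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import AlignIO

logger = logging.getLogger(__name__)

__all__ = [
    "AMINO_ACIDS",
    "AnnotatedAlignment",
    "FlankMatrix",
    "LogoColumn",
    "read_alignment",
    "read_sites",
    "extract_flanks",
    "logo_data",
    "logo_frame",
    "junction_residues",
    "plus1_summary",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
GAP_CHARS = set("-.")


class AnnotatedAlignment:
    """A protein alignment with annotated intein insertion blocks.

    Parameters
    ----------
    sequences:
        Mapping of sequence id -> aligned sequence (equal lengths, gaps
        allowed as ``-`` or ``.``).
    sites:
        Mapping of site name -> (start, end) alignment-column interval of
        the intein block, 0-based half-open. Intervals must be disjoint and
        within bounds.
    invasion_threshold:
        Minimum fraction of ungapped columns inside a block for a sequence
        to count as invaded there (default 0.5).
    """

    def __init__(
        self,
        sequences: dict[str, str],
        sites: dict[str, tuple[int, int]],
        invasion_threshold: float = 0.5,
    ):
        if not sequences:
            raise ValueError("alignment is empty")
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        (self.length,) = lengths
        ivals = sorted(sites.values())
        for start, end in ivals:
            if not (0 <= start < end <= self.length):
                raise ValueError(f"site interval {(start, end)} out of bounds")
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError("intein block intervals overlap")
        self.sequences = {k: str(v).upper() for k, v in sequences.items()}
        self.sites = dict(sites)
        self.invasion_threshold = invasion_threshold

    @property
    def ids(self) -> list[str]:
        return list(self.sequences)

    def is_invaded(self, site: str, seq_id: str) -> bool:
        start, end = self._site(site)
        block = self.sequences[seq_id][start:end]
        ungapped = sum(1 for c in block if c not in GAP_CHARS)
        return ungapped / (end - start) >= self.invasion_threshold

    def invasion_status(self, site: str) -> dict[str, bool]:
        return {sid: self.is_invaded(site, sid) for sid in self.sequences}

    def to_occupancy_frame(self) -> pd.DataFrame:
        """Site-per-column presence/absence DataFrame (taxa x sites)."""
        return pd.DataFrame(
            {site: pd.Series(self.invasion_status(site)) for site in self.sites}
        )

    def _site(self, site: str) -> tuple[int, int]:
        try:
            return self.sites[site]
        except KeyError:
            raise KeyError(f"unannotated site {site!r}; known: {sorted(self.sites)}") from None


@dataclass
class FlankMatrix:
    """Position-by-residue counts around one insertion site for one partition.

    Positions run -w..-1 then +1..+w (no position 0; the insertion point is
    between residues). ``counts`` has one row per position over the 20
    amino acids; ``coverage[p]`` is the number of sequences contributing a
    residue at position p.
    """

    site: str
    partition: str  # "invaded" | "uninvaded"
    w: int
    counts: np.ndarray = field(repr=False)
    coverage: np.ndarray = field(repr=False)
    n_sequences: int = 0

    @property
    def positions(self) -> list[int]:
        return list(range(-self.w, 0)) + list(range(1, self.w + 1))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.positions, columns=list(AMINO_ACIDS))
        df.index.name = "position"
        return df

    def column(self, position: int) -> np.ndarray:
        return self.counts[self.positions.index(position)]


@dataclass
class LogoColumn:
    """Residue frequencies and information content for one flank position."""

    position: int
    frequencies: dict[str, float]
    entropy: float  # Shannon, bits
    information: float  # log2(20) - H - e_n, clamped to [0, log2 20]
    coverage: int


def read_alignment(path: str, fmt: str | None = None) -> dict[str, str]:
    """Read a FASTA or NEXUS protein alignment into an id -> row mapping."""
    if fmt is None:
        with open(path) as fh:
            head = fh.read(6)
        fmt = "nexus" if head.upper().startswith("#NEXUS") else "fasta"
    aln = AlignIO.read(path, fmt)
    return {rec.id: str(rec.seq) for rec in aln}


def read_sites(path: str) -> dict[str, tuple[int, int]]:
    """Read site annotations from a TSV with columns site, start, end."""
    df = pd.read_csv(path, sep="\t")
    need = {"site", "start", "end"}
    if not need <= set(df.columns):
        raise ValueError(f"site annotation TSV needs columns {sorted(need)}")
    return {str(r.site): (int(r.start), int(r.end)) for r in df.itertuples()}


def _walk_flanks(row: str, start: int, end: int, w: int) -> tuple[list[str], list[str]]:
    """Up to w ungapped residues left of ``start`` and right of ``end``.

    Left list is ordered -1, -2, ...; right list +1, +2, ...
    """
    left: list[str] = []
    i = start - 1
    while i >= 0 and len(left) < w:
        if row[i] not in GAP_CHARS:
            left.append(row[i])
        i -= 1
    right: list[str] = []
    i = end
    while i < len(row) and len(right) < w:
        if row[i] not in GAP_CHARS:
            right.append(row[i])
        i += 1
    return left, right


def extract_flanks(
    aln: AnnotatedAlignment, site: str, w: int = 20
) -> tuple[FlankMatrix, FlankMatrix]:
    """Flank residue counts around ``site``, split by invasion status.

    Returns (invaded, uninvaded) matrices. Sequences with fewer than ``w``
    residues available on a side are included with reduced coverage (logged).
    """
    if w < 1:
        raise ValueError("window width must be >= 1")
    start, end = aln._site(site)
    mats = {
        part: FlankMatrix(
            site=site,
            partition=part,
            w=w,
            counts=np.zeros((2 * w, 20)),
            coverage=np.zeros(2 * w, dtype=int),
        )
        for part in ("invaded", "uninvaded")
    }
    short = 0
    for sid, row in aln.sequences.items():
        part = "invaded" if aln.is_invaded(site, sid) else "uninvaded"
        m = mats[part]
        m.n_sequences += 1
        left, right = _walk_flanks(row, start, end, w)
        if len(left) < w or len(right) < w:
            short += 1
        for k, res in enumerate(left):  # k=0 is position -1 -> row index w-1
            j = _AA_INDEX.get(res)
            if j is not None:
                m.counts[w - 1 - k, j] += 1
                m.coverage[w - 1 - k] += 1
        for k, res in enumerate(right):  # k=0 is position +1 -> row index w
            j = _AA_INDEX.get(res)
            if j is not None:
                m.counts[w + k, j] += 1
                m.coverage[w + k] += 1
    if short:
        logger.warning(
            "extract_flanks(%s): %d sequence(s) had fewer than %d residues on a side",
            site, short, w,
        )
    return mats["invaded"], mats["uninvaded"]


def logo_data(m: FlankMatrix) -> list[LogoColumn]:
    """Per-position frequencies and small-sample-corrected information.

    Positions with zero coverage are omitted with a warning.
    """
    cols: list[LogoColumn] = []
    max_ic = math.log2(20)
    for i, pos in enumerate(m.positions):
        n = int(m.coverage[i])
        if n == 0:
            logger.warning("logo_data(%s/%s): zero coverage at %+d; omitted", m.site, m.partition, pos)
            continue
        f = m.counts[i] / n
        nz = f[f > 0]
        H = float(-(nz * np.log2(nz)).sum())
        e_n = 19.0 / (2.0 * math.log(2) * n)
        ic = min(max(max_ic - H - e_n, 0.0), max_ic)
        cols.append(
            LogoColumn(
                position=pos,
                frequencies={aa: float(x) for aa, x in zip(AMINO_ACIDS, f)},
                entropy=H,
                information=ic,
                coverage=n,
            )
        )
    return cols


def logo_frame(columns: list[LogoColumn]) -> pd.DataFrame:
    """Logo columns as a tidy DataFrame consumable by standard logo plotters."""
    rows = []
    for c in columns:
        row = {"position": c.position, "coverage": c.coverage,
               "entropy": c.entropy, "information": c.information}
        row.update(c.frequencies)
        rows.append(row)
    return pd.DataFrame(rows)


def junction_residues(aln: AnnotatedAlignment, site: str, seq_id: str) -> tuple[str, str]:
    """The nearest ungapped residues at −1 and +1 of the insertion point."""
    start, end = aln._site(site)
    row = aln.sequences[seq_id]
    left, right = _walk_flanks(row, start, end, 1)
    if not left or not right:
        raise ValueError(f"sequence {seq_id!r} has an entirely gapped flank at site {site!r}")
    return left[0], right[0]


def plus1_summary(invaded: FlankMatrix, uninvaded: FlankMatrix) -> pd.DataFrame:
    """Residue-by-partition counts at the +1 position (no test attached)."""
    if invaded.n_sequences == 0 or uninvaded.n_sequences == 0:
        raise ValueError("both partitions must be nonempty")
    df = pd.DataFrame(
        {
            "invaded": invaded.column(+1),
            "uninvaded": uninvaded.column(+1),
        },
        index=list(AMINO_ACIDS),
    )
    df.index.name = "residue"
    return df[(df["invaded"] > 0) | (df["uninvaded"] > 0)]
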