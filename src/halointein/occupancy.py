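"""Taxon-by-site intein presence/absence tables and pattern statistics.

An :class:`OccupancyTable` records, for each taxon, which of the four intein
insertion sites (a, b, c, d) are occupied. From it we derive

* observed counts of the 16 joint presence/absence patterns,
* the expected pattern counts if sites invaded independently at their
  marginal frequencies (``E_p = N * prod_s f_s^{p_s} (1-f_s)^{1-p_s}``),
* the projection onto the four-state a/d occupancy coding used by the
  Markov models, and
* per-genus summaries of a-only / d-only / both / neither.

Mini-inteins (inteins lacking a homing endonuclease) count as *present* for
all occupancy purposes; the full/mini distinction is carried separately.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ctmc import STATES

__all__ = [
    "SITES",
    "OccupancyTable",
    "PatternDistribution",
    "read_table",
    "count_patterns",
    "expected_independent",
    "to_ctmc_states",
    "genus_summary",
    "chisquare_independence",
]

SITES: tuple[str, ...] = ("a", "b", "c", "d")

_TRUTHY = {"1", "present", "true", "yes", "+"}
_FALSY = {"0", "absent", "false", "no", "-", ""}


class OccupancyTable:
    """Presence/absence of inteins at sites a–d for a set of taxa.

    Parameters
    ----------
    data:
        DataFrame indexed by unique taxon labels with boolean columns
        ``a, b, c, d``; an optional ``genus`` column; optional boolean
        ``<site>_full`` columns flagging full (HEN-carrying) inteins.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dupes = sorted(data.index[data.index.duplicated()].unique())
            raise ValueError(f"duplicate taxon labels: {dupes}")
        if len(data) < 1:
            raise ValueError("occupancy table is empty")
        missing = [s for s in SITES if s not in data.columns]
        if missing:
            raise ValueError(f"missing site columns: {missing}")
        df = data.copy()
        for s in SITES:
            if df[s].isna().any():
                bad = df.index[df[s].isna()].tolist()
                raise ValueError(f"unfilled cells at site {s}: {bad[:5]}")
            df[s] = df[s].astype(bool)
        self.data = df

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def has_genus(self) -> bool:
        return "genus" in self.data.columns

    def presence(self) -> np.ndarray:
        """N x 4 boolean matrix in site order a, b, c, d."""
        return self.data[list(SITES)].to_numpy(dtype=bool)

    def marginals(self) -> dict[str, float]:
        m = self.presence().mean(axis=0)
        return dict(zip(SITES, map(float, m)))

    def to_tsv(self, path: str | None = None) -> str:
        out = self.data.copy()
        for s in SITES:
            out[s] = out[s].astype(int)
        text = out.to_csv(sep="\t", index_label="taxon")
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass
class PatternDistribution:
    """Observed and/or expected counts over the 16 joint site patterns.

    Patterns are keyed by strings like ``"a--d"`` (sites present shown by
    letter, absent by ``-``, in a,b,c,d order). Expected counts are reals.
    """

    observed: dict[str, float]
    expected: dict[str, float] | None
    marginals: dict[str, float]
    n: int

    @staticmethod
    def pattern_name(bits: tuple[int, int, int, int]) -> str:
        return "".join(s if b else "-" for s, b in zip(SITES, bits))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for bits in _all_patterns():
            p = self.pattern_name(bits)
            row = {"pattern": p, "observed": self.observed.get(p, 0.0)}
            if self.expected is not None:
                row["expected"] = self.expected.get(p, 0.0)
            rows.append(row)
        return pd.DataFrame(rows)

    def marginal(self, sites_present: str) -> tuple[float, float | None]:
        """Observed (and expected) count of taxa carrying all given sites.

        ``sites_present`` e.g. ``"ad"`` sums over patterns with a and d
        present regardless of b, c.
        """
        need = set(sites_present)
        obs = exp = 0.0
        for bits in _all_patterns():
            name = self.pattern_name(bits)
            present = {s for s, b in zip(SITES, bits) if b}
            if need <= present:
                obs += self.observed.get(name, 0.0)
                if self.expected is not None:
                    exp += self.expected.get(name, 0.0)
        return obs, (exp if self.expected is not None else None)


def _all_patterns():
    for i in range(16):
        yield tuple(int(b) for b in format(i, "04b"))


def _parse_cell(v, where: str) -> bool:
    s = str(v).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"unparseable presence/absence cell {v!r} at {where}")


def read_table(source: str | io.TextIOBase) -> OccupancyTable:
    """Read a TSV with a ``taxon`` column (or first column) and site columns.

    Cells may be 0/1, present/absent, true/false, +/-. Extra columns named
    ``genus`` and ``<site>_full`` are preserved; unknown columns raise.
    """
    df = pd.read_csv(source, sep="\t", dtype=str)
    if df.empty or df.shape[1] < 2:
        raise ValueError("empty or column-less occupancy table")
    first = df.columns[0]
    if first.lower() in ("taxon", "taxa", "label", "strain"):
        df = df.set_index(first)
    else:
        df = df.set_index(first)
    df.index = df.index.astype(str)
    known = set(SITES) | {"genus"} | {f"{s}_full" for s in SITES}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise ValueError(f"unknown columns in occupancy table: {unknown}")
    out = {}
    for s in SITES:
        if s not in df.columns:
            # only the modeled sites are mandatory; b and c default to absent
            if s in ("b", "c"):
                out[s] = [False] * len(df)
                continue
            raise ValueError(f"missing site column {s!r}")
        out[s] = [
            _parse_cell(v, f"taxon {t!r}, site {s}") for t, v in df[s].items()
        ]
    res = pd.DataFrame(out, index=df.index)
    if "genus" in df.columns:
        res["genus"] = df["genus"]
    for s in SITES:
        col = f"{s}_full"
        if col in df.columns:
            res[col] = [
                _parse_cell(v, f"taxon {t!r}, column {col}") for t, v in df[col].items()
            ]
    return OccupancyTable(res)


def count_patterns(table: OccupancyTable) -> PatternDistribution:
    """Observed counts of the 16 joint patterns plus per-site marginals."""
    pres = table.presence().astype(int)
    observed: dict[str, float] = {}
    for bits in _all_patterns():
        name = PatternDistribution.pattern_name(bits)
        observed[name] = float(np.all(pres == np.array(bits), axis=1).sum())
    return PatternDistribution(
        observed=observed, expected=None, marginals=table.marginals(), n=table.n
    )


def expected_independent(table: OccupancyTable) -> PatternDistribution:
    """Expected pattern counts under independent random invasion.

    Each site invades independently with its observed marginal frequency;
    expected counts are reals and sum to N exactly.
    """
    dist = count_patterns(table)
    f = np.array([dist.marginals[s] for s in SITES])
    expected: dict[str, float] = {}
    for bits in _all_patterns():
        name = PatternDistribution.pattern_name(bits)
        b = np.array(bits)
        expected[name] = float(table.n * np.prod(np.where(b, f, 1 - f)))
    dist.expected = expected
    return dist


def to_ctmc_states(table: OccupancyTable) -> dict[str, str]:
    """Project onto the four a/d occupancy states ("--", "-D", "A-", "AD").

    Sites b and c are ignored; mini-inteins count as present.
    """
    out = {}
    for taxon, row in table.data.iterrows():
        a, d = bool(row["a"]), bool(row["d"])
        out[taxon] = STATES[2 * a + d]
    return out


def genus_summary(table: OccupancyTable) -> pd.DataFrame:
    """Per-genus counts of a-only, d-only, both, neither (sites b, c ignored)."""
    if not table.has_genus:
        raise ValueError("occupancy table has no genus labels")
    df = table.data
    cat = np.select(
        [df["a"] & ~df["d"], ~df["a"] & df["d"], df["a"] & df["d"]],
        ["a_only", "d_only", "both"],
        default="neither",
    )
    out = (
        pd.crosstab(df["genus"], cat)
        .reindex(columns=["a_only", "d_only", "both", "neither"], fill_value=0)
        .rename_axis(index="genus", columns=None)
    )
    out["total"] = out.sum(axis=1)
    return out


def chisquare_independence(dist: PatternDistribution) -> tuple[float, float]:
    """Exploratory chi-square of observed vs independence-expected counts.

    Degrees of freedom: 16 patterns - 1 - 4 estimated marginals = 11. The
    usual large-sample caveats apply (small expected cells); no test is
    attached to the main outputs by default.
    """
    import scipy.stats

    if dist.expected is None:
        raise ValueError("distribution has no expected counts")
    obs = np.array([dist.observed[PatternDistribution.pattern_name(b)] for b in _all_patterns()])
    exp = np.array([dist.expected[PatternDistribution.pattern_name(b)] for b in _all_patterns()])
    mask = exp > 0
    stat = float(np.sum((obs[mask] - exp[mask]) ** 2 / exp[mask]))
    df = 16 - 1 - 4
    return stat, float(scipy.stats.chi2.sf(stat, df))
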