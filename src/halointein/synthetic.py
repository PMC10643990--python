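"""Generators for every input the pipeline consumes, with known ground truth.

Covers: birth–death/Yule trees (via dendropy), Gillespie simulation of the
four-state intein occupancy process along a tree under either transition
model, bundled tree+tip-state datasets for parameter-recovery experiments,
annotated alignments with intein blocks and configurable flank composition
(e.g. the serine/proline +1 dichotomy at an MCM-d-like site), and proteomes
with planted full/mini inteins for the PSSM scanner.

All generators are deterministic given (seed, config); one global seed
expands into independent per-component substreams so components can be
regenerated independently. Branch lengths are in time units and the CTMC
rates are per unit branch length — no separate calibration step.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .ctmc import MODELS, STATES, STATE_INDEX, TransitionModel, build_rate_matrix
from .flanks import AMINO_ACIDS, AnnotatedAlignment
from .inteinscan import PSSM, build_pssm
from .occupancy import OccupancyTable
from .treekit import Tree

__all__ = [
    "SimConfig",
    "SimHistory",
    "SimDataset",
    "simulate_tree",
    "simulate_history",
    "simulate_dataset",
    "synth_alignment",
    "synth_proteome",
    "synth_block_alignment",
    "make_motif_set",
    "history_event_stats",
]

# roughly haloarchaeal: acidic-residue-rich proteome composition
_EXTEIN_FREQS = {
    "A": 0.09, "C": 0.01, "D": 0.09, "E": 0.08, "F": 0.03, "G": 0.08,
    "H": 0.02, "I": 0.04, "K": 0.03, "L": 0.08, "M": 0.02, "N": 0.03,
    "P": 0.05, "Q": 0.03, "R": 0.07, "S": 0.06, "T": 0.07, "V": 0.08,
    "W": 0.01, "Y": 0.03,
}
assert abs(sum(_EXTEIN_FREQS.values()) - 1.0) < 1e-12


@dataclass
class SimConfig:
    """Study conditions for the generators.

    Tree: a Yule (``death_rate=0``) or birth–death process conditioned on
    ``n_tips`` extant tips, branch lengths in time units. Trait process:
    per-transition rates of the chosen model (default 1.0 each — order
    unity events per unit branch length, comparable to the gain/loss regime
    the recovery experiments probe). Sequence fixtures: intein block length,
    +1-residue composition per invasion status (site d defaults to the
    serine-in-invaded / mostly-proline-in-uninvaded dichotomy), and whether
    planted inteins carry HEN blocks.
    """

    n_tips: int = 100
    birth_rate: float = 1.0
    death_rate: float = 0.0
    model: str = "no_cohoming"
    rates: dict[str, float] | None = None
    root_state: str = "--"
    seed: int = 0
    # alignment fixtures
    extein_columns: int = 400
    intein_columns: int = 60
    site_columns: dict[str, int] = field(default_factory=lambda: {"a": 120, "d": 260})
    plus1_invaded: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"a": {"S": 1.0}, "d": {"S": 1.0}}
    )
    plus1_uninvaded: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"a": {"S": 1.0}, "d": {"P": 0.9, "S": 0.1}}
    )
    minus1_residues: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {"a": ("K",), "d": ("R", "D")}
    )
    # proteome fixtures
    n_proteins: int = 20
    protein_length: tuple[int, int] = (300, 600)
    with_hen: bool = True

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("need at least 2 tips")
        if not (self.birth_rate > self.death_rate >= 0):
            raise ValueError("need birth_rate > death_rate >= 0")
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.root_state not in STATE_INDEX:
            raise ValueError(f"unknown root state {self.root_state!r}")

    def rate_vector(self) -> np.ndarray:
        m = MODELS[self.model]
        if self.rates is None:
            return np.ones(m.k)
        missing = [t for t in m.transition_names if t not in self.rates]
        if missing:
            raise ValueError(f"rates missing for transitions: {missing}")
        return np.array([float(self.rates[t]) for t in m.transition_names])


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class SimHistory:
    """A simulated trait history: per-branch event lists plus tip states.

    ``events`` maps each node's id (see ``node_ids``) to the ordered list of
    (time along the branch leading to it, from_state, to_state).
    """

    tree: Tree
    model: str
    root_state: str
    events: dict[int, list[tuple[float, str, str]]]
    tip_states: dict[str, str]
    seed: int

    def replay(self) -> dict[str, str]:
        """Recompute tip states by replaying events from the root state."""
        dtree = self.tree.dendropy_tree
        ids = _node_ids(dtree)
        state_at: dict[int, str] = {ids[id(dtree.seed_node)]: self.root_state}
        out: dict[str, str] = {}
        for nd in dtree.preorder_node_iter():
            nid = ids[id(nd)]
            if nd is dtree.seed_node:
                continue
            s = state_at[ids[id(nd.parent_node)]]
            for _, frm, to in self.events.get(nid, []):
                if frm != s:
                    raise RuntimeError("inconsistent event chain")
                s = to
            state_at[nid] = s
            if nd.is_leaf():
                out[nd.taxon.label] = s
        return out


@dataclass
class SimDataset:
    """Tree + tip states + the generating rates, ready for refitting."""

    tree: Tree
    history: SimHistory
    tip_states: dict[str, str]
    model: str
    rates: dict[str, float]
    seed: int

    def occupancy_table(self) -> OccupancyTable:
        rows = {}
        for taxon, s in self.tip_states.items():
            rows[taxon] = {"a": s[0] == "A", "b": False, "c": False, "d": s[1] == "D"}
        return OccupancyTable(pd.DataFrame.from_dict(rows, orient="index"))

    def states_tsv(self, path: str | None = None) -> str:
        lines = ["taxon\tstate"] + [f"{t}\t{s}" for t, s in self.tip_states.items()]
        text = "\n".join(lines) + "\n"
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _node_ids(dtree: dendropy.Tree) -> dict[int, int]:
    return {id(nd): k for k, nd in enumerate(dtree.postorder_node_iter())}


def simulate_tree(cfg: SimConfig) -> Tree:
    """A rooted birth–death tree with ``cfg.n_tips`` extant tips.

    Deterministic given ``cfg.seed``; tip labels T1..Tn as assigned by the
    simulator. The process stops at the moment the n-th lineage appears, so
    every extant tip is then extended by the exponential waiting time of
    the n-lineage epoch — the tree stays ultrametric, no two tips coincide,
    and the expected Yule crown depth is exactly ``sum_{k=2..n} 1/(k*lambda)``.
    """
    ss = np.random.SeedSequence(cfg.seed).spawn(2)
    rng = random.Random(int(ss[0].generate_state(1)[0] % (2**31)))
    dtree = treesim.birth_death_tree(
        birth_rate=cfg.birth_rate,
        death_rate=cfg.death_rate,
        num_extant_tips=cfg.n_tips,
        rng=rng,
        repeat_until_success=True,
    )
    ext = np.random.default_rng(ss[1]).exponential(
        1.0 / (cfg.n_tips * (cfg.birth_rate + cfg.death_rate))
    )
    for lf in dtree.leaf_node_iter():
        lf.edge.length = (lf.edge.length or 0.0) + ext
    dtree.seed_node.edge.length = None
    return Tree(dtree)


def simulate_history(
    tree: Tree,
    model: TransitionModel | str,
    rates,
    root_state: str = "--",
    seed: int = 0,
) -> SimHistory:
    """Gillespie simulation of the occupancy process along each branch.

    In state s, the waiting time to the next event is exponential with rate
    ``-Q[s, s]`` and the next state is drawn proportional to the off-diagonal
    row ``Q[s, .]``; events beyond the branch end are discarded.
    """
    if isinstance(model, str):
        model = MODELS[model]
    Q = build_rate_matrix(model, rates)
    rng = np.random.default_rng(seed)
    dtree = tree.dendropy_tree
    ids = _node_ids(dtree)
    state_at: dict[int, int] = {ids[id(dtree.seed_node)]: STATE_INDEX[root_state]}
    events: dict[int, list[tuple[float, str, str]]] = {}
    tip_states: dict[str, str] = {}
    for nd in dtree.preorder_node_iter():
        if nd is dtree.seed_node:
            continue
        nid = ids[id(nd)]
        s = state_at[ids[id(nd.parent_node)]]
        blen = nd.edge.length or 0.0
        t = 0.0
        ev: list[tuple[float, str, str]] = []
        while True:
            total = -Q[s, s]
            if total <= 0:
                break
            t += rng.exponential(1.0 / total)
            if t > blen:
                break
            probs = Q[s].copy()
            probs[s] = 0.0
            nxt = int(rng.choice(4, p=probs / probs.sum()))
            ev.append((t, STATES[s], STATES[nxt]))
            s = nxt
        if ev:
            events[nid] = ev
        state_at[nid] = s
        if nd.is_leaf():
            tip_states[nd.taxon.label] = STATES[s]
    return SimHistory(
        tree=tree,
        model=model.name,
        root_state=root_state,
        events=events,
        tip_states=tip_states,
        seed=seed,
    )


def simulate_dataset(cfg: SimConfig) -> SimDataset:
    """Tree + trait history + tip-state table under the configured model."""
    tree_rng, hist_rng = np.random.SeedSequence(cfg.seed).spawn(2)
    tree = simulate_tree(replace(cfg, seed=int(tree_rng.generate_state(1)[0] % (2**31))))
    hist_seed = int(hist_rng.generate_state(1)[0] % (2**31))
    model = MODELS[cfg.model]
    rv = cfg.rate_vector()
    hist = simulate_history(tree, model, rv, cfg.root_state, seed=hist_seed)
    return SimDataset(
        tree=tree,
        history=hist,
        tip_states=hist.tip_states,
        model=cfg.model,
        rates=dict(zip(model.transition_names, map(float, rv))),
        seed=cfg.seed,
    )


def history_event_stats(histories) -> tuple[dict[str, float], dict[tuple[str, str], int]]:
    """Occupancy time per state and event counts per transition.

    Accepts one history or a list; empirical rate estimates are
    counts[(s, t)] / time_in_state[s].
    """
    if isinstance(histories, SimHistory):
        histories = [histories]
    time_in: dict[str, float] = {s: 0.0 for s in STATES}
    counts: dict[tuple[str, str], int] = {}
    for h in histories:
        dtree = h.tree.dendropy_tree
        ids = _node_ids(dtree)
        state_at = {ids[id(dtree.seed_node)]: h.root_state}
        for nd in dtree.preorder_node_iter():
            if nd is dtree.seed_node:
                continue
            nid = ids[id(nd)]
            s = state_at[ids[id(nd.parent_node)]]
            blen = nd.edge.length or 0.0
            prev_t = 0.0
            for t, frm, to in h.events.get(nid, []):
                time_in[s] += t - prev_t
                counts[(frm, to)] = counts.get((frm, to), 0) + 1
                prev_t = t
                s = to
            time_in[s] += blen - prev_t
            state_at[nid] = s
    return time_in, counts


# -- sequence fixtures ----------------------------------------------------


def _draw_seq(rng: np.random.Generator, n: int, freqs: dict[str, float] | None = None) -> str:
    f = freqs or _EXTEIN_FREQS
    aas = list(f)
    p = np.array([f[a] for a in aas])
    return "".join(rng.choice(aas, size=n, p=p / p.sum()))


def _draw_from(rng: np.random.Generator, dist: dict[str, float]) -> str:
    aas = list(dist)
    p = np.array([dist[a] for a in aas], dtype=float)
    return str(rng.choice(aas, p=p / p.sum()))


def synth_alignment(cfg: SimConfig, tip_states: dict[str, str], seed: int | None = None) -> AnnotatedAlignment:
    """An extein scaffold with intein blocks for invaded taxa.

    Every row shares an i.i.d. extein scaffold layout; at each annotated
    site, invaded rows carry ``cfg.intein_columns`` intein residues and
    uninvaded rows an all-gap block of the same width. The residues at the
    insertion-point junctions follow the configured −1 and +1 composition
    rules (per invasion status), emulating a conserved site (a) and an
    S/P-dichotomous site (d).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    site_state = {"a": lambda s: s[0] == "A", "d": lambda s: s[1] == "D"}
    order = sorted(cfg.site_columns, key=cfg.site_columns.get)
    scaffold = _draw_seq(rng, cfg.extein_columns)
    rows: dict[str, str] = {}
    sites: dict[str, tuple[int, int]] = {}
    # site intervals in final alignment coordinates
    offset = 0
    for s in order:
        col = cfg.site_columns[s]
        sites[s] = (col + offset, col + offset + cfg.intein_columns)
        offset += cfg.intein_columns
    for taxon, state in tip_states.items():
        pieces = []
        prev = 0
        row_scaffold = list(scaffold)
        for s in order:
            col = cfg.site_columns[s]
            invaded = site_state[s](state)
            # junction residues live on the extein scaffold around `col`
            row_scaffold[col - 1] = str(rng.choice(cfg.minus1_residues[s]))
            rule = cfg.plus1_invaded[s] if invaded else cfg.plus1_uninvaded[s]
            row_scaffold[col] = _draw_from(rng, rule)
            block = (
                _draw_seq(rng, cfg.intein_columns)
                if invaded
                else "-" * cfg.intein_columns
            )
            pieces.append("".join(row_scaffold[prev:col]) + block)
            prev = col
        pieces.append("".join(row_scaffold[prev:]))
        rows[taxon] = "".join(pieces)
    return AnnotatedAlignment(rows, sites)


def make_motif_set(n_motifs: int, length: int, seed: int = 0, prefix: str = "motif") -> dict[str, str]:
    """Fixed random consensus motifs (deterministic given seed)."""
    rng = np.random.default_rng(seed)
    return {f"{prefix}{i+1}": _draw_seq(rng, length) for i in range(n_motifs)}


def synth_block_alignment(
    consensus: str, n_seqs: int = 8, sub_rate: float = 0.1, seed: int = 0
) -> list[str]:
    """Mutated copies of a consensus, for building a PSSM block."""
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_seqs):
        row = [
            c if rng.random() >= sub_rate else str(rng.choice(list(AMINO_ACIDS)))
            for c in consensus
        ]
        rows.append("".join(row))
    return rows


@dataclass
class SynthProteome:
    """Planted-intein proteome plus its ground truth and scanner inputs."""

    proteome: dict[str, str]
    truth: pd.DataFrame  # seq_id, offset, length, category
    intein_pssms: list[PSSM]
    hen_pssms: list[PSSM]
    seed: int

    def write_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"; seed={self.seed}\n")
            for sid, seq in self.proteome.items():
                fh.write(f">{sid}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")


def _intein_sequence(
    rng: np.random.Generator,
    splice_motifs: dict[str, str],
    hen_motifs: dict[str, str],
    full: bool,
) -> str:
    """N-splicing motif + (optionally HEN blocks) + C-splicing motif.

    Linkers are kept short enough that the scanner's hit-merging (default
    gap 150) sees one region per intein.
    """
    n_motif, c_motif = splice_motifs["intein_N"], splice_motifs["intein_C"]
    parts = [n_motif, _draw_seq(rng, 20)]
    if full:
        for name in sorted(hen_motifs):
            parts.append(hen_motifs[name])
            parts.append(_draw_seq(rng, 10))
    parts.append(_draw_seq(rng, 10))
    parts.append(c_motif)
    return "".join(parts)


def synth_proteome(
    cfg: SimConfig,
    n_full: int = 8,
    n_mini: int = 5,
    seed: int | None = None,
) -> SynthProteome:
    """Random host proteins with planted full/mini inteins at known offsets.

    ``n_full`` + ``n_mini`` inteins are planted one-per-protein in the first
    proteins; remaining proteins stay intein-free. PSSMs for the two
    splicing-region motifs and the four HEN blocks are built from mutated
    block alignments of the same consensus motifs the planter used.
    """
    base_seed = cfg.seed if seed is None else seed
    rng_motif, rng_host, rng_blocks = _substreams(base_seed, 3)
    splice = make_motif_set(2, 25, seed=int(rng_motif.integers(2**31)), prefix="intein_")
    splice = {"intein_N": splice["intein_1"], "intein_C": splice["intein_2"]}
    hen = make_motif_set(4, 12, seed=int(rng_motif.integers(2**31)), prefix="hen")

    n_planted = n_full + n_mini
    if n_planted > cfg.n_proteins:
        raise ValueError("more planted inteins than proteins")
    lo, hi = cfg.protein_length
    proteome: dict[str, str] = {}
    truth_rows = []
    categories = ["full"] * n_full + ["mini"] * n_mini
    for i in range(cfg.n_proteins):
        sid = f"prot{i+1}"
        host = _draw_seq(rng_host, int(rng_host.integers(lo, hi + 1)))
        if i < n_planted:
            full = categories[i] == "full"
            intein = _intein_sequence(rng_host, splice, hen if cfg.with_hen else {}, full and cfg.with_hen)
            pos = int(rng_host.integers(0, len(host)))
            host = host[:pos] + intein + host[pos:]
            truth_rows.append(
                {"seq_id": sid, "offset": pos, "length": len(intein),
                 "category": "full" if (full and cfg.with_hen) else "mini"}
            )
        proteome[sid] = host
    intein_pssms = [
        build_pssm(
            synth_block_alignment(seq, seed=int(rng_blocks.integers(2**31))), name=name
        )
        for name, seq in splice.items()
    ]
    hen_pssms = [
        build_pssm(
            synth_block_alignment(seq, seed=int(rng_blocks.integers(2**31))), name=name
        )
        for name, seq in sorted(hen.items())
    ]
    truth = pd.DataFrame(truth_rows, columns=["seq_id", "offset", "length", "category"])
    return SynthProteome(
        proteome=proteome,
        truth=truth,
        intein_pssms=intein_pssms,
        hen_pssms=hen_pssms,
        seed=base_seed,
    )
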