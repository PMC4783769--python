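"""Discrete morphological characters from morphometric variables.

The directional-evolution screen nominates inter-landmark distances (e.g.
LM1-LM3 and LM1-LM5, in micrometres, per-species medians) whose values are
discretized into character states with fixed cut-offs; the resulting
species x character matrix can be exported to NEXUS for parsimony software
and scored on candidate topologies with the Fitch algorithm.

Qualitative anchor-shape characters (scimitar vs sickle shaft, U vs V
root) are assigned by inspecting PC-ordered shapes and are accepted here
as user-supplied state columns rather than derived automatically; see
:func:`suggest_shape_states` for a clearly-heuristic PC1-sign suggestion.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from anchorgm.phylo import Phylogeny

logger = logging.getLogger(__name__)


@dataclass
class CharacterDefinition:
    name: str
    variable: str
    states: dict[int, str]  # state code -> description


@dataclass
class CharacterMatrix:
    """Species x discrete character states (small nonnegative integers)."""

    data: pd.DataFrame  # index: species; integer state columns
    definitions: list[CharacterDefinition] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.isna().to_numpy().any():
            raise ValueError("character matrix contains missing states")
        self.data = self.data.astype(int)
        if (self.data.to_numpy() < 0).any():
            raise ValueError("character states must be nonnegative integers")

    @property
    def n_species(self) -> int:
        return self.data.shape[0]

    @property
    def n_characters(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# Discretization rules (lengths in micrometres, per-species medians)

def _state_lm13(length: float) -> int:
    # (0) 15 µm or less; (1) greater than 15 µm
    return 0 if length <= 15.0 else 1


def _state_v15(length: float) -> int:
    # (0) < 15 µm; (1) 15-25 µm (closed interval); (2) > 25 µm
    if length < 15.0:
        return 0
    if length <= 25.0:
        return 1
    return 2


def _state_d15(length: float) -> int:
    # (0) 15-25 µm; (1) > 25 µm — no state is declared below 15 µm
    if length < 15.0:
        raise ValueError(
            f"dorsal LM1-LM5 length {length} µm is below the declared state space "
            "(states start at 15 µm); extend the rule explicitly if your taxa fall there"
        )
    if length <= 25.0:
        return 0
    return 1


_RULES = {
    "ventral_LM1_LM3": (_state_lm13, {0: "15 µm or less", 1: "greater than 15 µm"}),
    "dorsal_LM1_LM3": (_state_lm13, {0: "15 µm or less", 1: "greater than 15 µm"}),
    "ventral_LM1_LM5": (_state_v15, {0: "less than 15 µm", 1: "15-25 µm", 2: "greater than 25 µm"}),
    "dorsal_LM1_LM5": (_state_d15, {0: "15-25 µm", 1: "greater than 25 µm"}),
}


def discretize_value(character: str, length_um: float) -> int:
    """State code for one character and one length (µm). Monotone in length."""
    if character not in _RULES:
        raise KeyError(f"unknown character {character!r}; known: {sorted(_RULES)}")
    if not np.isfinite(length_um) or length_um <= 0:
        raise ValueError("length must be positive and finite")
    return _RULES[character][0](float(length_um))


def discretize_lengths(lengths: pd.DataFrame) -> CharacterMatrix:
    """Discretize per-species median inter-landmark lengths into characters.

    ``lengths`` must be indexed by species with columns among
    ``ventral_LM1_LM3``, ``dorsal_LM1_LM3``, ``ventral_LM1_LM5``,
    ``dorsal_LM1_LM5`` (micrometres).
    """
    unknown = [c for c in lengths.columns if c not in _RULES]
    if unknown:
        raise KeyError(f"unknown character columns: {unknown}")
    data = pd.DataFrame(
        {c: [discretize_value(c, v) for v in lengths[c]] for c in lengths.columns},
        index=lengths.index,
    )
    defs = [CharacterDefinition(name=c, variable=c, states=_RULES[c][1]) for c in lengths.columns]
    return CharacterMatrix(data=data, definitions=defs)


def suggest_shape_states(pc1_scores: pd.Series) -> pd.Series:
    """HEURISTIC: 2-state shaft-shape suggestion from the sign of shape PC1.

    Positive shape-PC1 species tend toward sickle-shaped shafts and
    negative ones toward scimitar-shaped shafts in anchor morphospaces, but
    the assignment is advisory only — qualitative characters should be
    coded by inspecting the PC-ordered shapes.
    """
    logger.warning("suggest_shape_states is a heuristic PC1-sign suggestion; verify by inspection")
    return (pc1_scores > 0).astype(int).rename("shaft_shape_suggested")


# ---------------------------------------------------------------------------
# NEXUS export / import

def _quote_label(label: str) -> str:
    if re.search(r"\s", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_nexus(matrix: CharacterMatrix, path) -> None:
    """Write a standard-data NEXUS file (DATA block, SYMBOLS from observed states).

    Limited to single-digit state codes (at most 10 states per matrix);
    species labels containing whitespace are quoted. Missing data would be
    written as '?', but the matrix type forbids missing states.
    """
    states = sorted(set(matrix.data.to_numpy().ravel().tolist()))
    if any(s > 9 for s in states):
        raise ValueError("NEXUS standard data limited to single-digit states (0-9)")
    symbols = " ".join(str(s) for s in states)
    width = max(len(str(sp)) for sp in matrix.data.index) + 2
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"    DIMENSIONS NTAX={matrix.n_species} NCHAR={matrix.n_characters};\n")
        fh.write(f'    FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=?;\n')
        fh.write("    MATRIX\n")
        for sp, row in matrix.data.iterrows():
            label = _quote_label(str(sp))
            fh.write(f"    {label:<{width}} {''.join(str(v) for v in row)}\n")
        fh.write("    ;\nEND;\n")


def read_nexus(path) -> CharacterMatrix:
    """Read back a standard-data NEXUS matrix written by :func:`write_nexus`."""
    with open(path) as fh:
        text = fh.read()
    m = re.search(r"MATRIX(.*?);", text, flags=re.S | re.I)
    if m is None:
        raise ValueError("no MATRIX block found")
    rows = {}
    for line in m.group(1).strip().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("'"):
            qm = re.match(r"'((?:[^']|'')*)'\s+(\S+)", line)
            if qm is None:
                raise ValueError(f"malformed matrix row: {line!r}")
            label, states = qm.group(1).replace("''", "'"), qm.group(2)
        else:
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"malformed matrix row: {line!r}")
            label, states = parts
        rows[label] = [int(ch) for ch in states]
    ncols = len(next(iter(rows.values())))
    data = pd.DataFrame.from_dict(rows, orient="index", columns=[f"char{i+1}" for i in range(ncols)])
    data.index.name = "species"
    return CharacterMatrix(data=data)


# ---------------------------------------------------------------------------
# Fitch parsimony scoring

def fitch_score(
    tree: Phylogeny | str, matrix: CharacterMatrix
) -> tuple[pd.Series, int]:
    """Parsimony length of each character on a tree (Fitch, unordered states).

    Polytomies are resolved into an arbitrary binary caterpillar before the
    bottom-up set pass; the Fitch length is independent of rooting, so the
    score applies to the unrooted topology. Returns the per-character
    lengths and their total. Raises if any species in the matrix is absent
    from the tree or vice versa.
    """
    if not isinstance(tree, Phylogeny):
        tree = Phylogeny.from_newick(tree, assume_unit_lengths=True)
    tips = set(tree.tip_labels)
    species = set(map(str, matrix.data.index))
    if tips != species:
        raise ValueError(
            f"tip/species mismatch: tree-only {sorted(tips - species)}, "
            f"matrix-only {sorted(species - tips)}"
        )

    def score_char(states: dict[str, int]) -> int:
        changes = 0

        def down(node):
            nonlocal changes
            if node.is_leaf():
                return frozenset([states[node.taxon.label]])
            children = node.child_nodes()
            # binary caterpillar resolution of polytomies
            sets = [down(ch) for ch in children]
            acc = sets[0]
            for s in sets[1:]:
                inter = acc & s
                if inter:
                    acc = inter
                else:
                    acc = acc | s
                    changes += 1
            return acc

        down(tree.tree.seed_node)
        return changes

    lengths = pd.Series(
        {
            col: score_char(dict(zip(map(str, matrix.data.index), matrix.data[col])))
            for col in matrix.data.columns
        },
        name="parsimony_length",
    )
    return lengths, int(lengths.sum())
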