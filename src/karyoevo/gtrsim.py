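"""Site-independent sequence simulation under the general time-reversible
(GTR) substitution model.

The rate matrix is built from six exchangeabilities (order AC, AG, AT, CG,
CT, GT) and stationary base frequencies, then normalised to one expected
substitution per unit branch length, so branch lengths are substitutions per
site.  The root sequence is drawn from the stationary distribution and
evolved down the tree with per-branch transition matrices expm(Q t).
"""

from __future__ import annotations

from typing import Sequence

import dendropy
import numpy as np
from scipy.linalg import expm

__all__ = ["gtr_rate_matrix", "simulate_sequences_gtr"]

BASES = "ACGT"
_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


def gtr_rate_matrix(
    exchangeabilities: Sequence[float], base_freqs: Sequence[float]
) -> np.ndarray:
    """Normalised GTR rate matrix Q with q_ij = s_ij * pi_j (i != j)."""
    s = np.asarray(exchangeabilities, dtype=float)
    pi = np.asarray(base_freqs, dtype=float)
    if s.shape != (6,) or np.any(s < 0):
        raise ValueError("need 6 nonnegative exchangeabilities (AC,AG,AT,CG,CT,GT)")
    if pi.shape != (4,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("base_freqs must be a 4-simplex")
    Q = np.zeros((4, 4))
    for rate, (i, j) in zip(s, _PAIRS):
        Q[i, j] = rate * pi[j]
        Q[j, i] = rate * pi[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()  # expected substitutions per unit time
    if mu <= 0:
        raise ValueError("degenerate rate matrix (all exchangeabilities zero?)")
    return Q / mu


def simulate_sequences_gtr(
    tree: str,
    length: int,
    exchangeabilities: Sequence[float] = (1, 1, 1, 1, 1, 1),
    base_freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
) -> dict[str, str]:
    """Simulate one sequence per tip of ``tree`` (newick, substitutions/site
    branch lengths); returns ``{tip label: sequence}``."""
    if length < 1:
        raise ValueError("length must be >= 1")
    Q = gtr_rate_matrix(exchangeabilities, base_freqs)
    pi = np.asarray(base_freqs, dtype=float)
    t = dendropy.Tree.get(data=tree, schema="newick")
    rng = np.random.default_rng(seed)

    root_states = rng.choice(4, size=length, p=pi)
    out: dict[str, str] = {}

    def descend(node: dendropy.Node, states: np.ndarray) -> None:
        for child in node.child_nodes():
            bl = child.edge.length or 0.0
            if bl < 0:
                raise ValueError("negative branch length")
            if bl == 0:
                child_states = states
            else:
                P = expm(Q * bl)
                P = np.clip(P, 0, None)
                P /= P.sum(axis=1, keepdims=True)
                child_states = np.empty_like(states)
                for parent_state in range(4):
                    mask = states == parent_state
                    n = int(mask.sum())
                    if n:
                        child_states[mask] = rng.choice(4, size=n, p=P[parent_state])
            if child.is_leaf():
                out[child.taxon.label] = "".join(BASES[s] for s in child_states)
            else:
                descend(child, child_states)

    if t.seed_node.is_leaf():
        out[t.seed_node.taxon.label] = "".join(BASES[s] for s in root_states)
    descend(t.seed_node, root_states)
    return out
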