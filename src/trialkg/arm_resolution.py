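"""Separating analysis-section groups into intervention vs comparator.

The registry labels arms as Experimental/Comparator only in the study-design
section; the statistical-analysis blocks list bare group titles, and those
titles are not always verbatim copies of the design titles ("Canagliflozin
50 mg" vs "Canagliflozin (JNJ-28431754)"). Each analysis group therefore
inherits the role of the design arm whose title it is most similar to.

Similarity is computed by a pluggable embedding backend. The default is a
deterministic character 3-gram term-frequency cosine over lowercased,
whitespace-normalized titles: no model download, fully reproducible. A
transformer sentence-encoder satisfying the same ``embed`` contract can be
registered as an alternative backend.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Protocol, Sequence

import numpy as np

from trialkg.records import DesignArm, normalize_ws

logger = logging.getLogger(__name__)


class EmbeddingBackend(Protocol):
    """Contract: map texts to fixed-length vectors, deterministically."""

    name: str

    def embed(self, texts: Sequence[str]) -> np.ndarray: ...


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two vectors, in [-1, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"vector length mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for zero-norm vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


class NgramCosineBackend:
    """Character n-gram term-frequency embedding (default n=3).

    Titles are lowercased and whitespace-normalized, then decomposed into
    overlapping character n-grams; the vector is the gram-count profile over
    the vocabulary of the batch. Titles shorter than n contribute themselves
    as a single gram so nothing embeds to the zero vector.
    """

    def __init__(self, n: int = 3) -> None:
        self.n = n
        self.name = f"char{n}gram-tf"

    def _grams(self, text: str) -> list[str]:
        t = normalize_ws(text).lower()
        if len(t) < self.n:
            return [t] if t else []
        return [t[i : i + self.n] for i in range(len(t) - self.n + 1)]

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        grams_per_text = [self._grams(t) for t in texts]
        vocab = sorted({g for grams in grams_per_text for g in grams})
        index = {g: i for i, g in enumerate(vocab)}
        mat = np.zeros((len(texts), max(len(vocab), 1)), dtype=float)
        for row, grams in enumerate(grams_per_text):
            for g in grams:
                mat[row, index[g]] += 1.0
        return mat


_BACKENDS: dict[str, Callable[[], EmbeddingBackend]] = {
    "char3gram": lambda: NgramCosineBackend(3),
    "char2gram": lambda: NgramCosineBackend(2),
}


def register_backend(name: str, factory: Callable[[], EmbeddingBackend]) -> None:
    """Register an embedding backend factory (e.g. a transformer adapter)."""
    _BACKENDS[name] = factory


def available_backends() -> list[str]:
    return sorted(_BACKENDS)


def get_backend(name: str = "char3gram") -> EmbeddingBackend:
    try:
        return _BACKENDS[name]()
    except KeyError:
        raise KeyError(
            f"unknown embedding backend {name!r}; available: {', '.join(available_backends())}"
        ) from None


@dataclass
class ArmAssignment:
    """Resolution of a two-group analysis into intervention and comparator."""

    nct_id: str
    intervention_group: str
    comparator_group: str
    score_intervention: float
    score_comparator: float
    method: str  # exact | embedding


def _norm_key(title: str) -> str:
    return normalize_ws(title).lower()


def resolve_arms(
    group_titles: Sequence[str],
    design_arms: Sequence[DesignArm],
    backend: Optional[EmbeddingBackend] = None,
    nct_id: str = "NCT00000000",
    min_score: Optional[float] = None,
) -> Optional[ArmAssignment]:
    """Assign intervention/comparator roles to exactly two analysis groups.

    Requires at least one experimental and one comparator design arm;
    otherwise the comparison cannot be oriented and ``None`` is returned
    (the row is excluded). Exact case-insensitive title equality with a
    design arm fixes that group's role outright and no similarity score can
    override it. Otherwise each group inherits the role of its most similar
    design arm; if both groups inherit the same role, the bijective pairing
    (one group per role) with the larger summed similarity wins. Similarity
    ties are broken by design-arm document order.

    ``min_score``, if set, turns assignments whose weaker similarity falls
    below the threshold into exclusions. Off by default: the procedure is a
    bare argmax.
    """
    if len(group_titles) != 2:
        raise ValueError(f"resolve_arms requires exactly two group titles, got {len(group_titles)}")
    exp_arms = [a for a in design_arms if a.role == "experimental"]
    comp_arms = [a for a in design_arms if a.role == "comparator"]
    if not exp_arms or not comp_arms:
        logger.debug("%s: no valid experimental/comparator design labels; row excluded", nct_id)
        return None

    backend = backend or get_backend()
    g0, g1 = (normalize_ws(t) for t in group_titles)
    if _norm_key(g0) == _norm_key(g1):
        logger.debug("%s: identical group titles %r; row excluded", nct_id, g0)
        return None

    roled = [(a, "experimental") for a in exp_arms] + [(a, "comparator") for a in comp_arms]
    texts = [g0, g1] + [a.title for a, _ in roled]
    vecs = backend.embed(texts)
    # similarity of each group against each roled design arm; exact title
    # equality is pinned to 1.0 and dominates any embedding score
    sims = np.empty((2, len(roled)))
    exact = np.zeros((2, len(roled)), dtype=bool)
    for i, g in enumerate((g0, g1)):
        for j, (arm, _) in enumerate(roled):
            if _norm_key(g) == _norm_key(arm.title):
                sims[i, j] = 1.0
                exact[i, j] = True
            else:
                try:
                    sims[i, j] = cosine_similarity(vecs[i], vecs[2 + j])
                except ValueError:
                    sims[i, j] = -1.0

    def best(i: int, role: Optional[str] = None) -> tuple[int, float]:
        """Index and score of group i's best design arm, optionally within a role."""
        cand = [
            j for j, (_, r) in enumerate(roled)
            if role is None or r == role
        ]
        # exact matches dominate; ties broken by document order (first max)
        j_best = max(cand, key=lambda j: (exact[i, j], sims[i, j], -j))
        return j_best, sims[i, j_best]

    j0, s0 = best(0)
    j1, s1 = best(1)
    role0, role1 = roled[j0][1], roled[j1][1]

    if role0 == role1:
        # both groups argmax into the same role: choose the bijective
        # pairing (one intervention, one comparator) maximizing total
        # similarity, exact matches still dominating
        _, e0 = best(0, "experimental")
        _, c0 = best(0, "comparator")
        _, e1 = best(1, "experimental")
        _, c1 = best(1, "comparator")
        pair_a = e0 + c1  # g0 intervention, g1 comparator
        pair_b = e1 + c0  # g1 intervention, g0 comparator
        if exact[0, j0] != exact[1, j1]:
            # the exactly-matched group keeps its role
            g0_is_intervention = (exact[0, j0] and role0 == "experimental") or (
                exact[1, j1] and role1 == "comparator"
            )
        else:
            g0_is_intervention = pair_a >= pair_b
        if g0_is_intervention:
            role0, role1 = "experimental", "comparator"
            s0, s1 = e0, c1
        else:
            role0, role1 = "comparator", "experimental"
            s0, s1 = c0, e1

    if role0 == "experimental":
        assignment = ArmAssignment(
            nct_id=nct_id,
            intervention_group=g0,
            comparator_group=g1,
            score_intervention=float(s0),
            score_comparator=float(s1),
            method="exact" if (exact[0].any() and exact[1].any()) else "embedding",
        )
    else:
        assignment = ArmAssignment(
            nct_id=nct_id,
            intervention_group=g1,
            comparator_group=g0,
            score_intervention=float(s1),
            score_comparator=float(s0),
            method="exact" if (exact[0].any() and exact[1].any()) else "embedding",
        )
    if min_score is not None and min(assignment.score_intervention, assignment.score_comparator) < min_score:
        logger.debug("%s: assignment below min score %.3f; row excluded", nct_id, min_score)
        return None
    return assignment


def evaluate_assignments(
    assignments: Sequence[ArmAssignment],
    gold: Sequence[tuple[str, str, str]],
) -> tuple[float, float]:
    """Accuracy of predicted (intervention, comparator) titles against gold.

    ``gold`` rows are ``(nct_id, intervention_title, comparator_title)``,
    aligned with ``assignments`` positionally by (nct_id, title pair).

    Returns the fraction of exact title matches per role.
    """
    if len(assignments) != len(gold):
        raise ValueError(
            f"assignment/gold length mismatch: {len(assignments)} vs {len(gold)}"
        )
    offenders = [
        (a.nct_id, g[0]) for a, g in zip(assignments, gold) if a.nct_id != g[0]
    ]
    if offenders:
        raise ValueError(f"unaligned rows (assignment nct_id != gold nct_id): {offenders[:5]}")
    if not assignments:
        return (1.0, 1.0)
    n = len(assignments)
    ok_i = sum(1 for a, g in zip(assignments, gold) if _norm_key(a.intervention_group) == _norm_key(g[1]))
    ok_c = sum(1 for a, g in zip(assignments, gold) if _norm_key(a.comparator_group) == _norm_key(g[2]))
    return (ok_i / n, ok_c / n)
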