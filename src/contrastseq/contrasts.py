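"""GLM design coding and automatic contrast generation.

The expression model for a complete factorial design with biological
factors A (I modalities) and B (J modalities) and an optional replicate
factor (R modalities) uses treatment (reference-level) coding:

    log mu = intercept + replicate deviations + A deviations
             + B deviations [+ AxB interaction deviations]

giving ``1 + (R-1) + (I-1) + (J-1) + (I-1)(J-1)`` coefficients with
interaction.  Every contrast is defined by zero-sum weights on the
condition means (combinations of biological modalities, at the reference
replicate) and realized as a vector over the coefficient basis.

Three families are generated automatically for every pair of modalities:
*averaged* differences (unweighted mean over the other factor),
*per-modality* differences (at a fixed modality of the other factor), and
*interaction* differences-of-differences.  For two factors the total count
is ``C(I,2)(J+1) + C(J,2)(I+1) + C(I,2)C(J,2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations

import numpy as np

from .datatypes import DesignTable, ProjectError

__all__ = [
    "GLMDesign",
    "Contrast",
    "build_design_matrix",
    "generate_contrasts",
    "contrast_to_vector",
    "parse_contrast_name",
]

Condition = tuple[str, ...]


@dataclass
class GLMDesign:
    design: DesignTable
    with_interaction: bool
    coefficient_names: list[str]
    design_matrix: np.ndarray  # samples x coefficients, {0,1}
    condition_map: dict[Condition, np.ndarray]  # condition -> coefficient vector

    @property
    def n_coefficients(self) -> int:
        return len(self.coefficient_names)

    def condition_vector(self, condition: Condition) -> np.ndarray:
        try:
            return self.condition_map[condition]
        except KeyError:
            raise ProjectError(f"unknown condition {condition!r}") from None


@dataclass
class Contrast:
    """Zero-sum weights on condition means plus the realized coefficient vector."""

    name: str
    kind: str  # "averaged" | "per_modality" | "interaction"
    weights_on_conditions: dict[Condition, Fraction]
    vector: np.ndarray = field(default=None)  # over GLM coefficients

    def __post_init__(self) -> None:
        total = sum(self.weights_on_conditions.values())
        if total != 0:
            raise ValueError(f"contrast {self.name}: condition weights sum to {total}")

    @property
    def is_degenerate(self) -> bool:
        return self.vector is not None and not np.any(self.vector)


def _condition_coefficients(
    names: list[str],
    bio: list[str],
    levels: dict[str, list[str]],
    with_interaction: bool,
) -> dict[Condition, np.ndarray]:
    """Coefficient combination giving each condition mean at reference replicate."""
    pos = {n: i for i, n in enumerate(names)}
    cmap: dict[Condition, np.ndarray] = {}
    if len(bio) == 1:
        (fa,) = bio
        for a in levels[fa]:
            v = np.zeros(len(names))
            v[pos["Intercept"]] = 1.0
            if a != levels[fa][0]:
                v[pos[f"{fa}_{a}"]] = 1.0
            cmap[(a,)] = v
    else:
        fa, fb = bio
        ref_a, ref_b = levels[fa][0], levels[fb][0]
        for a in levels[fa]:
            for b in levels[fb]:
                v = np.zeros(len(names))
                v[pos["Intercept"]] = 1.0
                if a != ref_a:
                    v[pos[f"{fa}_{a}"]] = 1.0
                if b != ref_b:
                    v[pos[f"{fb}_{b}"]] = 1.0
                if with_interaction and a != ref_a and b != ref_b:
                    v[pos[f"{fa}_{a}:{fb}_{b}"]] = 1.0
                cmap[(a, b)] = v
    return cmap


def build_design_matrix(
    design: DesignTable, with_interaction: bool = True
) -> GLMDesign:
    """Treatment-coded design matrix in the fixed coefficient order
    (intercept; replicate; factor A; factor B; AxB interaction)."""
    design.check_complete()
    bio = design.biological_factors
    if len(bio) == 1:
        with_interaction = False
    levels = design.levels
    names = ["Intercept"]
    if design.replicate_factor is not None:
        rf = design.replicate_factor
        names += [f"{rf}_{m}" for m in levels[rf][1:]]
    for f in bio:
        names += [f"{f}_{m}" for m in levels[f][1:]]
    if with_interaction and len(bio) == 2:
        fa, fb = bio
        names += [
            f"{fa}_{a}:{fb}_{b}"
            for a in levels[fa][1:]
            for b in levels[fb][1:]
        ]
    pos = {n: i for i, n in enumerate(names)}
    x = np.zeros((len(design.sample_ids), len(names)))
    x[:, 0] = 1.0
    for si, s in enumerate(design.sample_ids):
        row = design.table.loc[s]
        if design.replicate_factor is not None:
            rf = design.replicate_factor
            if row[rf] != levels[rf][0]:
                x[si, pos[f"{rf}_{row[rf]}"]] = 1.0
        for f in bio:
            if row[f] != levels[f][0]:
                x[si, pos[f"{f}_{row[f]}"]] = 1.0
        if with_interaction and len(bio) == 2:
            fa, fb = bio
            if row[fa] != levels[fa][0] and row[fb] != levels[fb][0]:
                x[si, pos[f"{fa}_{row[fa]}:{fb}_{row[fb]}"]] = 1.0
    rank = np.linalg.matrix_rank(x)
    if rank < len(names):
        raise ProjectError(
            f"design matrix rank {rank} < {len(names)} coefficients"
        )
    if x.shape[0] < 2 * len(names):
        warnings.warn(
            f"only {x.shape[0]} samples for {len(names)} coefficients; "
            "advice: have at least twice as many observations as parameters "
            "(consider dropping the interaction)",
            stacklevel=2,
        )
    cmap = _condition_coefficients(names, bio, levels, with_interaction)
    return GLMDesign(design, with_interaction, names, x, cmap)


def contrast_to_vector(
    weights: dict[Condition, Fraction], glm_design: GLMDesign
) -> np.ndarray:
    """Realize condition weights on the coefficient basis.

    ``vector @ beta`` equals the weighted sum of condition log-means at the
    reference replicate; replicate coefficients always receive weight 0.
    """
    v = np.zeros(glm_design.n_coefficients)
    for cond, w in weights.items():
        v += float(w) * glm_design.condition_vector(cond)
    v[np.abs(v) < 1e-12] = 0.0
    return v


def generate_contrasts(
    glm_design: GLMDesign, include_degenerate: bool = False
) -> list[Contrast]:
    """All averaged, per-modality and interaction contrasts, automatically.

    Pair orientation is declaration order (first-appearing modality minus
    later-appearing).  Under an additive (no-interaction) model the
    interaction contrasts are identically zero on the coefficient basis;
    they are flagged degenerate and excluded unless requested.
    """
    design = glm_design.design
    bio = design.biological_factors
    levels = design.levels
    out: list[Contrast] = []

    def mk(name: str, kind: str, weights: dict[Condition, Fraction]) -> Contrast:
        c = Contrast(name, kind, weights)
        c.vector = contrast_to_vector(weights, glm_design)
        return c

    if len(bio) == 1:
        (fa,) = bio
        for a1, a2 in combinations(levels[fa], 2):
            out.append(
                mk(f"[{a1}-{a2}]", "averaged", {(a1,): Fraction(1), (a2,): Fraction(-1)})
            )
        return out

    fa, fb = bio
    la, lb = levels[fa], levels[fb]
    a_pairs = list(combinations(la, 2))
    b_pairs = list(combinations(lb, 2))

    for a1, a2 in a_pairs:  # A averaged over B
        w = {}
        for b in lb:
            w[(a1, b)] = Fraction(1, len(lb))
            w[(a2, b)] = Fraction(-1, len(lb))
        out.append(mk(f"[{a1}-{a2}]", "averaged", w))
    for a1, a2 in a_pairs:  # A at each modality of B
        for b in lb:
            out.append(
                mk(
                    f"[{b}_{a1}-{b}_{a2}]",
                    "per_modality",
                    {(a1, b): Fraction(1), (a2, b): Fraction(-1)},
                )
            )
    for b1, b2 in b_pairs:  # B averaged over A
        w = {}
        for a in la:
            w[(a, b1)] = Fraction(1, len(la))
            w[(a, b2)] = Fraction(-1, len(la))
        out.append(mk(f"[{b1}-{b2}]", "averaged", w))
    for b1, b2 in b_pairs:  # B at each modality of A
        for a in la:
            out.append(
                mk(
                    f"[{a}_{b1}-{a}_{b2}]",
                    "per_modality",
                    {(a, b1): Fraction(1), (a, b2): Fraction(-1)},
                )
            )
    for a1, a2 in a_pairs:  # differences of differences
        for b1, b2 in b_pairs:
            name = f"[{a1}_{b1}-{a1}_{b2}]-[{a2}_{b1}-{a2}_{b2}]"
            w = {
                (a1, b1): Fraction(1),
                (a1, b2): Fraction(-1),
                (a2, b1): Fraction(-1),
                (a2, b2): Fraction(1),
            }
            out.append(mk(name, "interaction", w))
    if not include_degenerate:
        out = [c for c in out if not c.is_degenerate]
    return out


def _match_pair(token: str, glm_design: GLMDesign) -> tuple[str, str] | None:
    """Split ``"<mod1>_<mod2>"`` into two known modalities (if possible)."""
    design = glm_design.design
    mods = {m for f in design.biological_factors for m in design.levels[f]}
    for i in range(len(token)):
        if token[i] == "_" and token[:i] in mods and token[i + 1 :] in mods:
            return token[:i], token[i + 1 :]
    return None


def parse_contrast_name(name: str, glm_design: GLMDesign) -> dict:
    """Recover kind and involved modalities from a generated contrast name."""
    design = glm_design.design
    mods = {m for f in design.biological_factors for m in design.levels[f]}

    def split_diff(body: str) -> tuple[str, str]:
        for i in range(1, len(body)):
            if body[i] == "-":
                return body[:i], body[i + 1 :]
        raise ValueError(f"cannot parse contrast name {name!r}")

    if "]-[" in name:
        left, right = name.split("]-[")
        t1, t2 = split_diff(left.strip("[]"))
        t3, t4 = split_diff(right.strip("[]"))
        pairs = [_match_pair(t, glm_design) for t in (t1, t2, t3, t4)]
        if any(p is None for p in pairs):
            raise ValueError(f"cannot parse contrast name {name!r}")
        return {
            "kind": "interaction",
            "a_pair": (pairs[0][0], pairs[2][0]),
            "b_pair": (pairs[0][1], pairs[1][1]),
        }
    body = name.strip("[]")
    # try plain modality pair first (averaged), else conditioned pair
    for i in range(1, len(body)):
        if body[i] == "-" and body[:i] in mods and body[i + 1 :] in mods:
            return {"kind": "averaged", "pair": (body[:i], body[i + 1 :])}
    t1, t2 = split_diff(body)
    p1, p2 = _match_pair(t1, glm_design), _match_pair(t2, glm_design)
    if p1 is None or p2 is None:
        raise ValueError(f"cannot parse contrast name {name!r}")
    return {"kind": "per_modality", "fixed": p1[0], "pair": (p1[1], p2[1])}
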