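"""Dempster-Shafer evidence combination.

A basic probability assignment (BPA, or mass function) distributes one unit
of belief over non-empty subsets (focal elements) of a finite frame of
discernment. Two independent bodies of evidence are combined by Dempster's
rule: products of masses whose focal elements intersect are accumulated on
the intersection and renormalized by 1 - K, where the conflict coefficient
K is the total mass the pair places on incompatible (empty-intersection)
hypotheses. K = 1 (total conflict) makes the combination undefined.
"""

from __future__ import annotations

import json
from functools import reduce
from itertools import product
from typing import Iterable, Mapping, Sequence

__all__ = ["MassFunction", "conflict", "combine_bpa", "combine_many", "TotalConflictError"]

_MASS_TOL = 1e-9


class TotalConflictError(ValueError):
    """Dempster's rule is undefined for totally conflicting evidence (K = 1)."""


class MassFunction:
    """A basic probability assignment over a fixed frame of discernment.

    Parameters
    ----------
    frame:
        The hypothesis labels (mutually exclusive outcomes).
    masses:
        Map from focal elements (iterables of frame labels) to mass.
        Masses must be non-negative and sum to 1 within 1e-9.
    """

    def __init__(self, frame: Iterable[str], masses: Mapping[Iterable[str], float]):
        self.frame = frozenset(frame)
        if not self.frame:
            raise ValueError("frame of discernment must be non-empty")
        clean: dict[frozenset, float] = {}
        for subset, mass in masses.items():
            fs = frozenset(subset)
            if not fs:
                raise ValueError("focal elements must be non-empty subsets")
            if not fs <= self.frame:
                raise ValueError(f"focal element {sorted(fs)} outside the frame")
            if mass < 0:
                raise ValueError("masses must be non-negative")
            clean[fs] = clean.get(fs, 0.0) + float(mass)
        total = sum(clean.values())
        if abs(total - 1.0) > _MASS_TOL:
            raise ValueError(f"masses must sum to 1 (got {total})")
        self.masses = clean

    @classmethod
    def vacuous(cls, frame: Iterable[str]) -> "MassFunction":
        """All mass on the full frame: total ignorance, the identity of Dempster's rule."""
        frame = frozenset(frame)
        return cls(frame, {frame: 1.0})

    def __getitem__(self, subset: Iterable[str]) -> float:
        return self.masses.get(frozenset(subset), 0.0)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MassFunction):
            return NotImplemented
        if self.frame != other.frame:
            return False
        keys = set(self.masses) | set(other.masses)
        return all(abs(self[k] - other[k]) <= _MASS_TOL for k in keys)

    def __repr__(self) -> str:
        body = ", ".join(
            f"{{{','.join(sorted(k))}}}: {v:.4g}" for k, v in sorted(self.masses.items(), key=lambda kv: sorted(kv[0]))
        )
        return f"MassFunction({body})"

    def to_json(self) -> str:
        return json.dumps(
            {
                "frame": sorted(self.frame),
                "masses": [
                    {"subset": sorted(k), "mass": v} for k, v in self.masses.items()
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MassFunction":
        obj = json.loads(text)
        return cls(obj["frame"], {frozenset(e["subset"]): e["mass"] for e in obj["masses"]})


def _check_frames(m1: MassFunction, m2: MassFunction) -> None:
    if m1.frame != m2.frame:
        raise ValueError("mass functions must share the same frame of discernment")


def conflict(m1: MassFunction, m2: MassFunction) -> float:
    """Conflict coefficient K: total paired mass on empty intersections."""
    _check_frames(m1, m2)
    k = 0.0
    for (a1, v1), (a2, v2) in product(m1.masses.items(), m2.masses.items()):
        if not (a1 & a2):
            k += v1 * v2
    return min(k, 1.0)


def combine_bpa(m1: MassFunction, m2: MassFunction) -> MassFunction:
    """Dempster's rule: m(X) = (1/(1-K)) * sum over A1 ∩ A2 = X of m1(A1) m2(A2)."""
    _check_frames(m1, m2)
    k = conflict(m1, m2)
    if 1.0 - k <= _MASS_TOL:
        raise TotalConflictError("total conflict (K = 1): combination undefined")
    out: dict[frozenset, float] = {}
    for (a1, v1), (a2, v2) in product(m1.masses.items(), m2.masses.items()):
        inter = a1 & a2
        if inter:
            out[inter] = out.get(inter, 0.0) + v1 * v2
    norm = 1.0 - k
    return MassFunction(m1.frame, {k_: v / norm for k_, v in out.items()})


def combine_many(ms: Sequence[MassFunction]) -> MassFunction:
    """Left fold of Dempster's rule; order-independent by commutativity/associativity."""
    if not ms:
        raise ValueError("need at least one mass function")
    return reduce(combine_bpa, ms)
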