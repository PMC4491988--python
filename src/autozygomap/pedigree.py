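"""Pedigrees, kinship and inbreeding coefficients.

A pedigree is a directed parent->child structure over named individuals.
Founders (both parents unknown) are assumed non-inbred and mutually
unrelated, the standard base case of the recursive kinship computation.
The inbreeding coefficient F of an individual is the kinship coefficient
of its parents: the probability that two alleles sampled at a random
autosomal locus, one from each parent, are identical by descent.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

from .errors import PedigreeError, UnknownIndividualError, UnsupportedUnionError

AFFECTED = "affected"
UNAFFECTED = "unaffected"
UNKNOWN = "unknown"

MALE = 1
FEMALE = 2

UNION_TYPES = ("first-cousin", "double-first-cousin", "second-cousin")


@dataclass(frozen=True)
class Individual:
    """One pedigree member; ``father``/``mother`` are ids or ``None``."""

    iid: str
    father: str | None
    mother: str | None
    sex: int
    status: str = UNKNOWN

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


class Pedigree:
    """Validated pedigree supporting kinship/inbreeding queries.

    Validation enforces: every named parent exists, fathers are male and
    mothers female, founders have both parents absent (an individual with
    exactly one known parent is rejected), and the parent relation is
    acyclic.
    """

    def __init__(self, individuals: list[Individual], family_id: str = "FAM"):
        self.family_id = family_id
        self.members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.iid in self.members:
                raise PedigreeError(f"duplicate individual id {ind.iid!r}")
            self.members[ind.iid] = ind
        self._validate()
        self._kinship_cache: dict[tuple[str, str], float] = {}

    def _validate(self) -> None:
        for ind in self.members.values():
            if (ind.father is None) != (ind.mother is None):
                raise PedigreeError(
                    f"{ind.iid!r} has exactly one known parent; founders must have none"
                )
            for pid, want_sex, role in (
                (ind.father, MALE, "father"),
                (ind.mother, FEMALE, "mother"),
            ):
                if pid is None:
                    continue
                if pid not in self.members:
                    raise PedigreeError(f"{role} {pid!r} of {ind.iid!r} not in pedigree")
                if self.members[pid].sex != want_sex:
                    raise PedigreeError(f"{role} {pid!r} of {ind.iid!r} has wrong sex")
        # acyclicity via depth computation (raises on a parent cycle)
        self.depth  # noqa: B018

    @cached_property
    def depth(self) -> dict[str, int]:
        """Generation depth: founders 0, else 1 + max(parental depths)."""
        depth: dict[str, int] = {}
        state: dict[str, int] = {}  # 1 = in progress, 2 = done

        def visit(iid: str, chain: list[str]) -> int:
            if iid in depth:
                return depth[iid]
            if state.get(iid) == 1:
                raise PedigreeError(f"pedigree cycle involving {iid!r}")
            state[iid] = 1
            ind = self.members[iid]
            if ind.is_founder:
                d = 0
            else:
                d = 1 + max(visit(ind.father, chain), visit(ind.mother, chain))
            state[iid] = 2
            depth[iid] = d
            return d

        for iid in self.members:
            visit(iid, [])
        return depth

    @property
    def founders(self) -> list[str]:
        return [i for i, ind in self.members.items() if ind.is_founder]

    @property
    def affected(self) -> list[str]:
        return [i for i, ind in self.members.items() if ind.status == AFFECTED]

    def topological_order(self) -> list[str]:
        """Ids sorted parents-before-children (by depth, then insertion)."""
        order = list(self.members)
        return sorted(order, key=lambda i: (self.depth[i], order.index(i)))

    def __contains__(self, iid: str) -> bool:
        return iid in self.members

    def __len__(self) -> int:
        return len(self.members)

    def _require(self, iid: str) -> Individual:
        try:
            return self.members[iid]
        except KeyError:
            raise UnknownIndividualError(f"unknown individual id {iid!r}") from None

    def kinship(self, a: str, b: str) -> float:
        """Recursive kinship coefficient phi(a, b).

        phi(a, a) = (1 + F_a) / 2; for distinct individuals the recursion
        descends through the parents of the deeper of the two, with
        distinct founders unrelated by assumption.
        """
        self._require(a)
        self._require(b)
        key = (a, b) if a <= b else (b, a)
        if key in self._kinship_cache:
            return self._kinship_cache[key]
        ia, ib = self.members[a], self.members[b]
        if a == b:
            phi = 0.5 * (1.0 + self.inbreeding(a))
        else:
            # recurse on the deeper individual; equal depth means neither is
            # an ancestor of the other, so either choice is valid
            if self.depth[a] > self.depth[b]:
                a, b = b, a
                ia, ib = ib, ia
            if ib.is_founder:
                phi = 0.0
            else:
                phi = 0.5 * (self.kinship(a, ib.father) + self.kinship(a, ib.mother))
        self._kinship_cache[key] = phi
        return phi

    def inbreeding(self, iid: str) -> float:
        """Inbreeding coefficient F = kinship(father, mother); founders 0."""
        ind = self._require(iid)
        if ind.is_founder:
            return 0.0
        return self.kinship(ind.father, ind.mother)


def compute_inbreeding(pedigree: Pedigree, individual: str) -> float:
    """Inbreeding coefficient of ``individual`` (0 for founders)."""
    return pedigree.inbreeding(individual)


def build_consanguineous_pedigree(
    union_type: str, n_affected_children: int, family_id: str = "FAM"
) -> Pedigree:
    """Build a loop-containing pedigree whose final union is consanguineous.

    Supported unions: ``first-cousin`` (parents share one grandparental
    couple; offspring F = 1/16), ``double-first-cousin`` (parents share
    both grandparental couples; F = 1/8) and ``second-cousin`` (shared
    great-grandparental couple; F = 1/64).  Children of the final union
    are flagged affected; everyone else unaffected.
    """
    if n_affected_children < 1:
        raise ValueError("n_affected_children must be >= 1")
    if union_type not in UNION_TYPES:
        raise UnsupportedUnionError(
            f"union_type {union_type!r} not one of {UNION_TYPES}"
        )

    ind: list[Individual] = []

    def founder(iid: str, sex: int) -> str:
        ind.append(Individual(iid, None, None, sex, UNAFFECTED))
        return iid

    def child(iid: str, father: str, mother: str, sex: int, status=UNAFFECTED) -> str:
        ind.append(Individual(iid, father, mother, sex, status))
        return iid

    if union_type == "first-cousin":
        a1 = founder("GF1", MALE)
        a2 = founder("GM1", FEMALE)
        b1 = child("P1", a1, a2, MALE)
        b2 = child("P2", a1, a2, FEMALE)
        s1 = founder("S1", FEMALE)
        s2 = founder("S2", MALE)
        fa = child("FA", b1, s1, MALE)
        mo = child("MO", s2, b2, FEMALE)
    elif union_type == "double-first-cousin":
        a1 = founder("GF1", MALE)
        a2 = founder("GM1", FEMALE)
        d1 = founder("GF2", MALE)
        d2 = founder("GM2", FEMALE)
        b1 = child("P1", a1, a2, MALE)
        b2 = child("P2", a1, a2, FEMALE)
        e1 = child("P3", d1, d2, FEMALE)
        e2 = child("P4", d1, d2, MALE)
        fa = child("FA", b1, e1, MALE)
        mo = child("MO", e2, b2, FEMALE)
    else:  # second-cousin
        a1 = founder("GGF1", MALE)
        a2 = founder("GGM1", FEMALE)
        b1 = child("G1", a1, a2, MALE)
        b2 = child("G2", a1, a2, FEMALE)
        s1 = founder("S1", FEMALE)
        s2 = founder("S2", MALE)
        c1 = child("P1", b1, s1, MALE)
        c2 = child("P2", s2, b2, FEMALE)
        s3 = founder("S3", FEMALE)
        s4 = founder("S4", MALE)
        fa = child("FA", c1, s3, MALE)
        mo = child("MO", s4, c2, FEMALE)

    for k in range(1, n_affected_children + 1):
        sex = MALE if k % 2 == 1 else FEMALE
        child(f"C{k}", fa, mo, sex, AFFECTED)

    return Pedigree(ind, family_id=family_id)
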