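"""Pedigree representation, kinship coefficients and family structure.

A pedigree is a directed acyclic parent→child structure.  Every individual
has either zero or two recorded parents; records with a single known parent
are rejected at load time.  Kinship coefficients φ are computed by the
standard recursion with founders assumed non-inbred and mutually unrelated:

    φ(f, f')  = 0                       for distinct founders
    φ(x, x)   = ½ (1 + φ(father(x), mother(x)))
    φ(x, y)   = ½ (φ(father(x), y) + φ(mother(x), y))   x not ancestor of y

φ(i, j) is the probability that one allele drawn at random from i and one
from j at the same autosomal locus are identical by descent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


@dataclass(frozen=True)
class NuclearFamily:
    """A (father, mother) couple and all of their shared children."""

    father_id: str
    mother_id: str
    child_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.child_ids:
            raise PedigreeError("nuclear family must have at least one child")


@dataclass
class Pedigree:
    """Individuals with parent links plus the set of genotyped ids.

    ``individuals`` maps id -> (father_id | None, mother_id | None, sex).
    Sex codes are carried through but only used for parent-role checks.
    """

    individuals: dict[str, tuple[str | None, str | None, int]]
    genotyped: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._validate()
        self._order = self._topological_order()
        self._depth = {iid: i for i, iid in enumerate(self._order)}
        self._kinship_cache: dict[tuple[str, str], float] = {}

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        for iid, (fa, mo, _sex) in self.individuals.items():
            if (fa is None) != (mo is None):
                raise PedigreeError(f"individual {iid} has exactly one recorded parent")
            for pid in (fa, mo):
                if pid is not None and pid not in self.individuals:
                    raise PedigreeError(f"parent {pid} of {iid} not in pedigree")
        for iid in self.genotyped:
            if iid not in self.individuals:
                raise PedigreeError(f"genotyped id {iid} not in pedigree")

    def _topological_order(self) -> list[str]:
        """Founders-first order; raises on parent-relation cycles."""
        indeg = {iid: 0 for iid in self.individuals}
        children: dict[str, list[str]] = {iid: [] for iid in self.individuals}
        for iid, (fa, mo, _) in self.individuals.items():
            for pid in (fa, mo):
                if pid is not None:
                    indeg[iid] += 0  # counted below per distinct parent slot
            if fa is not None:
                indeg[iid] += 1
                children[fa].append(iid)
            if mo is not None:
                indeg[iid] += 1
                children[mo].append(iid)
        queue = sorted(iid for iid, d in indeg.items() if d == 0)
        order: list[str] = []
        while queue:
            nxt = queue.pop(0)
            order.append(nxt)
            ready = []
            for ch in children[nxt]:
                indeg[ch] -= 1
                if indeg[ch] == 0:
                    ready.append(ch)
            # keep deterministic founders-first order
            queue = sorted(queue + ready, key=lambda x: (self._gen_unknown(x), x))
        if len(order) != len(self.individuals):
            raise PedigreeError("cycle detected in parent relation")
        return order

    @staticmethod
    def _gen_unknown(_: str) -> int:
        return 0

    @property
    def ids(self) -> list[str]:
        """All ids in a deterministic founders-first topological order."""
        return list(self._order)

    def father(self, iid: str) -> str | None:
        return self.individuals[iid][0]

    def mother(self, iid: str) -> str | None:
        return self.individuals[iid][1]

    def sex(self, iid: str) -> int:
        return self.individuals[iid][2]

    def is_founder(self, iid: str) -> bool:
        return self.individuals[iid][0] is None

    def parents(self, iid: str) -> tuple[str, str] | None:
        fa, mo, _ = self.individuals[iid]
        if fa is None:
            return None
        return fa, mo  # type: ignore[return-value]

    def children_of(self, iid: str) -> list[str]:
        return [c for c, (fa, mo, _) in self.individuals.items() if iid in (fa, mo)]

    def descendants(self, iid: str) -> set[str]:
        """All strict descendants of ``iid``."""
        out: set[str] = set()
        stack = [iid]
        child_map: dict[str, list[str]] = {}
        for c, (fa, mo, _) in self.individuals.items():
            for p in (fa, mo):
                if p is not None:
                    child_map.setdefault(p, []).append(c)
        while stack:
            cur = stack.pop()
            for ch in child_map.get(cur, ()):
                if ch not in out:
                    out.add(ch)
                    stack.append(ch)
        return out

    # -- kinship -----------------------------------------------------------

    def kinship(self, i: str, j: str) -> float:
        """Recursive kinship coefficient φ(i, j) ∈ [0, 1]."""
        for iid in (i, j):
            if iid not in self.individuals:
                raise KeyError(f"unknown id {iid!r}")
        return self._phi(i, j)

    def _phi(self, i: str, j: str) -> float:
        key = (i, j) if i <= j else (j, i)
        hit = self._kinship_cache.get(key)
        if hit is not None:
            return hit
        if i == j:
            par = self.parents(i)
            val = 0.5 if par is None else 0.5 * (1.0 + self._phi(par[0], par[1]))
        else:
            # recurse on the individual that appears later in topological
            # order: it cannot be an ancestor of the other one
            a, b = (i, j) if self._depth[i] >= self._depth[j] else (j, i)
            par = self.parents(a)
            if par is None:
                val = 0.0
            else:
                val = 0.5 * (self._phi(par[0], b) + self._phi(par[1], b))
        self._kinship_cache[key] = val
        return val

    def kinship_matrix(self, ids: Sequence[str]):
        """Dense symmetric kinship matrix over ``ids`` (numpy array)."""
        import numpy as np

        n = len(ids)
        out = np.zeros((n, n))
        for a in range(n):
            for b in range(a, n):
                out[a, b] = out[b, a] = self.kinship(ids[a], ids[b])
        return out

    # -- derived structure -------------------------------------------------

    def quasi_founders(self) -> set[str]:
        """Genotyped individuals for whom both parents are not genotyped.

        These are the top of the genotyped sub-pedigree: either true
        founders or individuals whose recorded parents lack genotypes.
        """
        out = set()
        for iid in self.genotyped:
            par = self.parents(iid)
            if par is None or not (par[0] in self.genotyped and par[1] in self.genotyped):
                out.add(iid)
        return out

    def nuclear_families(self) -> list[NuclearFamily]:
        """One family per distinct parent couple with at least one child."""
        fams: dict[tuple[str, str], list[str]] = {}
        for iid in self._order:
            par = self.parents(iid)
            if par is not None:
                fams.setdefault(par, []).append(iid)
        return [
            NuclearFamily(fa, mo, tuple(children))
            for (fa, mo), children in sorted(fams.items())
        ]


def load_pedigree(path: str | Path, genotyped: Iterable[str] | None = None) -> Pedigree:
    """Load a whitespace-delimited pedigree file: id father mother sex.

    ``"0"`` denotes a missing parent.  Rows may appear in any order.
    """
    individuals: dict[str, tuple[str | None, str | None, int]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 4:
            raise PedigreeError(f"malformed pedigree row: {line!r}")
        iid, fa, mo, sex = fields[:4]
        if iid in individuals:
            raise PedigreeError(f"duplicate id {iid}")
        individuals[iid] = (
            None if fa == "0" else fa,
            None if mo == "0" else mo,
            int(sex),
        )
    geno = set(genotyped) if genotyped is not None else set(individuals)
    return Pedigree(individuals, genotyped=geno)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iid in ped.ids:
            fa, mo, sex = ped.individuals[iid]
            fh.write(f"{iid} {fa or 0} {mo or 0} {sex}\n")
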