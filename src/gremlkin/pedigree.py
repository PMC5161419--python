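"""Pedigree records and the pair sets that define environment matrices.

A nuclear family unit is one couple plus their common children.  The
derived pair sets are:

``couples``
    unordered pairs who are parents of at least one common child, or who
    are declared spouses in a sidecar file;
``full_sibs``
    pairs with both parents known and identical;
``parent_offspring``
    child paired with each known parent;
``nuclear_family``
    the union of the three sets above — co-membership of at least one
    nuclear family unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = ["Pedigree", "read_pedigree"]

Pair = frozenset  # unordered id pair


def _pair(a: str, b: str) -> frozenset:
    return frozenset((a, b))


@dataclass
class Pedigree:
    """Individuals with parent links and sex, plus derived pair sets."""

    records: list[tuple[str, str | None, str | None, int]]
    declared_spouses: set[frozenset] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate individual ids: {dup}")
        self._parents = {r[0]: (r[1], r[2]) for r in self.records}
        for iid, (f, m) in self._parents.items():
            if iid in (f, m):
                raise ValueError(f"individual {iid} listed as its own parent")
        self._check_acyclic()
        self._derive_pairs()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(iid: str) -> None:
            stack = [(iid, False)]
            while stack:
                node, processed = stack.pop()
                if processed:
                    state[node] = 1
                    continue
                if state.get(node) == 1:
                    continue
                if state.get(node) == 0:
                    raise ValueError(f"cyclic parentage involving {node}")
                state[node] = 0
                stack.append((node, True))
                for p in self._parents.get(node, (None, None)):
                    if p is not None and state.get(p) != 1:
                        if state.get(p) == 0:
                            raise ValueError(f"cyclic parentage involving {p}")
                        stack.append((p, False))

        for iid in self._parents:
            if state.get(iid) != 1:
                visit(iid)

    def _derive_pairs(self) -> None:
        couples: set[frozenset] = set(self.declared_spouses)
        sibs: set[frozenset] = set()
        par_off: set[frozenset] = set()
        present = set(self._parents)
        by_parents: dict[tuple[str, str], list[str]] = {}
        for iid, (f, m) in self._parents.items():
            if f is not None and m is not None:
                by_parents.setdefault((f, m), []).append(iid)
                if f in present and m in present:
                    couples.add(_pair(f, m))
            for p in (f, m):
                if p is not None and p in present:
                    par_off.add(_pair(iid, p))
        for kids in by_parents.values():
            for i, a in enumerate(kids):
                for b in kids[i + 1 :]:
                    sibs.add(_pair(a, b))
        self.couples = couples
        self.full_sibs = sibs
        self.parent_offspring = par_off
        self.nuclear_family = couples | sibs | par_off

    @property
    def individual_ids(self) -> list[str]:
        return [r[0] for r in self.records]

    def pair_set(self, kind: str) -> set[frozenset]:
        return {
            "C": self.couples,
            "S": self.full_sibs,
            "F": self.nuclear_family,
        }[kind]


def read_pedigree(path, spouse_path=None) -> Pedigree:
    """Parse whitespace-delimited id/father/mother/sex records.

    Parent codes "0" and "NA" mean unknown; sex is 1=male, 2=female,
    0=unknown (other codes warn and map to 0).
    """
    records = []
    for line in open(path):
        tok = line.split()
        if not tok:
            continue
        if len(tok) < 4:
            raise ValueError(f"pedigree row needs 4 columns, got: {line.strip()!r}")
        iid, f, m, sex = tok[:4]
        f = None if f in ("0", "NA") else f
        m = None if m in ("0", "NA") else m
        if sex not in ("0", "1", "2"):
            warnings.warn(f"unknown sex code {sex!r} for {iid}; treated as unknown")
            sex = "0"
        records.append((iid, f, m, int(sex)))
    spouses: set[frozenset] = set()
    if spouse_path is not None:
        for line in open(spouse_path):
            tok = line.split()
            if len(tok) >= 2:
                spouses.add(_pair(tok[0], tok[1]))
    return Pedigree(records, declared_spouses=spouses)
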