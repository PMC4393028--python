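"""Pedigree inbreeding coefficients with generation-depth truncation.

F_Ped is Wright's inbreeding coefficient, computed as the kinship of the
parents via the recursive tabular (additive-relationship) method. "Last k
generations" keeps ancestors reachable within k meioses of the focal animal;
anything deeper is treated as an unknown, unrelated founder with F = 0.
Pedigree completeness is the MacCluer-style index: the fraction of ancestor
slots that are filled, averaged over generations 1..k.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

UNKNOWN = {None, "", "0", 0}


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Parentage records: id -> (sire or None, dam or None)."""

    records: dict

    def __post_init__(self) -> None:
        clean = {}
        as_sire, as_dam = set(), set()
        for ind, (sire, dam) in self.records.items():
            sire = None if sire in UNKNOWN else str(sire)
            dam = None if dam in UNKNOWN else str(dam)
            clean[str(ind)] = (sire, dam)
            if sire:
                as_sire.add(sire)
            if dam:
                as_dam.add(dam)
        both = as_sire & as_dam
        if both:
            raise PedigreeError(f"ids used as both sire and dam: {sorted(both)[:5]}")
        self.records = clean
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 1 = visiting, 2 = done

        def visit(x: str) -> None:
            if state.get(x) == 2:
                return
            if state.get(x) == 1:
                raise PedigreeError(f"pedigree cycle involving {x}")
            state[x] = 1
            for p in self.parents(x):
                if p is not None:
                    visit(p)
            state[x] = 2

        for ind in self.records:
            visit(ind)

    def parents(self, ind: str) -> tuple:
        return self.records.get(ind, (None, None))

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        df = pd.read_csv(path, dtype=str).fillna("")
        cols = {c.lower(): c for c in df.columns}
        return cls(
            {
                row[cols["id"]]: (row[cols["sire"]], row[cols["dam"]])
                for _, row in df.iterrows()
            }
        )

    def depth_truncated(self, ind: str, max_depth: int | None) -> dict:
        """Parent links restricted to ancestors within max_depth meioses of ind."""
        if ind not in self.records:
            raise PedigreeError(f"unknown individual {ind!r}")
        if max_depth is None:
            return dict(self.records)
        mindepth = {ind: 0}
        frontier = [ind]
        while frontier:
            nxt = []
            for x in frontier:
                d = mindepth[x]
                if d >= max_depth:
                    continue
                for p in self.parents(x):
                    if p is not None and mindepth.get(p, d + 2) > d + 1:
                        mindepth[p] = d + 1
                        nxt.append(p)
            frontier = nxt
        trunc = {}
        for x in mindepth:
            sire, dam = self.parents(x)
            trunc[x] = (
                sire if sire in mindepth else None,
                dam if dam in mindepth else None,
            )
        return trunc


def _kinship(records: dict) -> "callable":
    """Memoised kinship function over a (possibly truncated) record dict."""
    # rank by generation height so recursion always descends to older animals
    rank: dict[str, int] = {}

    def height(x) -> int:
        if x is None or x not in records:
            return 0
        if x in rank:
            return rank[x]
        s, d = records[x]
        rank[x] = 1 + max(height(s), height(d))
        return rank[x]

    cache: dict[tuple, float] = {}

    def phi(a, b) -> float:
        if a is None or b is None:
            return 0.0
        key = (a, b) if a <= b else (b, a)
        if key in cache:
            return cache[key]
        if a == b:
            s, d = records.get(a, (None, None))
            val = 0.5 * (1.0 + phi(s, d))
        else:
            # recurse on the younger (taller) individual
            if height(a) < height(b):
                a, b = b, a
            s, d = records.get(a, (None, None))
            val = 0.5 * (phi(s, b) + phi(d, b))
        cache[key] = val
        return val

    return phi


def f_ped(ped: Pedigree, ind: str, max_depth: int | None = None) -> float:
    """Wright's inbreeding coefficient of ``ind``, pedigree truncated at depth.

    F(x) = kinship(sire, dam) = 0.5 * a(sire, dam); ancestors beyond
    ``max_depth`` meioses are unknown founders (F = 0, unrelated).
    """
    if max_depth is not None and max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    records = ped.depth_truncated(ind, max_depth)
    sire, dam = records.get(ind, (None, None))
    return _kinship(records)(sire, dam)


def completeness(ped: Pedigree, ind: str, max_depth: int) -> float:
    """Mean over generations g = 1..max_depth of known ancestor slots / 2^g."""
    if ind not in ped.records:
        raise PedigreeError(f"unknown individual {ind!r}")
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    fracs = []
    slots = [ind]
    for _g in range(1, max_depth + 1):
        parents: list = []
        for x in slots:
            if x is None:
                parents += [None, None]
            else:
                parents += list(ped.parents(x))
        known = sum(p is not None for p in parents)
        fracs.append(known / len(parents))
        slots = parents
    return sum(fracs) / len(fracs)


def delta_f_from_fped(mean_fped: float, n_generations: int) -> float:
    """Per-generation inbreeding increase as the simple average F/generations."""
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    return mean_fped / n_generations


def inbreeding_table(ped: Pedigree, ids: list, depths: tuple = (5, 11)) -> pd.DataFrame:
    rows = []
    for ind in ids:
        row = {"sample_id": ind}
        for d in depths:
            row[f"f_ped_{d}"] = f_ped(ped, ind, d)
            row[f"completeness_{d}"] = completeness(ped, ind, d)
        rows.append(row)
    return pd.DataFrame(rows)
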