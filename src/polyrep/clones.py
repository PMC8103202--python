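"""Clonal grouping of annotated hybridomas and oligoclonality metrics.

Two records are *clones* when they share heavy and kappa V genes, identical
CDR3 strings on both chains and identical V-region mutation sets; a record
sharing the genes and CDR3s whose mutation sets strictly contain another's
is *clonally related* — a lineage member that underwent further rounds of
hypermutation.  Grouping takes the transitive closure of these relations, so
an identical pair plus a related descendant forms one clone set.

CDR3 identity on both chains is required by default because the junction is
the clonal fingerprint and is not covered by V-mutation lists; a relaxed
mode (same length, >= ``min_cdr3_identity`` fraction of matching residues)
is available.  IgM and IgG records are grouped separately by default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from polyrep.annotate import NS
from polyrep.simulate import parse_mutations

MutSet = frozenset


@dataclass
class CloneMember:
    id: str
    status: str  # identical-clone | clonally-related
    extra_heavy: int
    extra_kappa: int


@dataclass
class CloneSet:
    set_id: str
    heavy_v: str
    kappa_v: str
    heavy_cdr3: str
    kappa_cdr3: str
    isotype: str
    members: list[CloneMember] = field(default_factory=list)

    @property
    def member_ids(self) -> frozenset[str]:
        return frozenset(m.id for m in self.members)

    def __len__(self) -> int:
        return len(self.members)


def _mutset(value) -> MutSet:
    if isinstance(value, (set, frozenset)):
        return frozenset(value)
    return frozenset(parse_mutations(value))


def _cdr3_compatible(a: str, b: str, require_identity: bool, min_identity: float) -> bool:
    if a == b:
        return True
    if require_identity or len(a) != len(b) or not a:
        return False
    matches = sum(x == y for x, y in zip(a, b))
    return matches / len(a) >= min_identity


def _related(ha: MutSet, ka: MutSet, hb: MutSet, kb: MutSet) -> bool:
    """Clone/related relation on mutation sets: one record's sets contain the other's."""
    return (ha <= hb and ka <= kb) or (hb <= ha and kb <= ka)


def group_clones(
    annotations: pd.DataFrame,
    *,
    require_cdr3_identity: bool = True,
    min_cdr3_identity: float = 0.9,
    group_by_isotype: bool = True,
) -> tuple[list[CloneSet], pd.DataFrame]:
    """Partition paired annotated records into clone sets.

    ``annotations`` needs columns id, heavy_v, kappa_v, heavy_cdr3,
    kappa_cdr3 and optionally isotype and heavy_mutations/kappa_mutations
    (serialized ``pos:from>to;...`` or sets; missing columns mean unmutated).
    Records lacking either chain (``NS``) are excluded from grouping.
    Returns the clone sets (multi-member only, members sorted by id) and a
    membership table with one row per grouped record.

    The output is a partition: no record appears in two sets, and it is
    invariant to input row order.
    """
    df = annotations.copy()
    for col in ("heavy_mutations", "kappa_mutations"):
        if col not in df.columns:
            df[col] = ""
    if "isotype" not in df.columns:
        df["isotype"] = ""

    usable = df[
        df["heavy_v"].ne(NS) & df["kappa_v"].ne(NS)
        & df["heavy_cdr3"].ne(NS) & df["kappa_cdr3"].ne(NS)
        & df["heavy_cdr3"].notna() & df["kappa_cdr3"].notna()
    ].sort_values("id")

    sets: list[CloneSet] = []
    rows: list[dict] = []
    keycols = ["heavy_v", "kappa_v"]
    if group_by_isotype:
        keycols = ["isotype"] + keycols

    for key, grp in usable.groupby(keycols, sort=True):
        recs = [
            {
                "id": r["id"],
                "h_cdr3": str(r["heavy_cdr3"]), "k_cdr3": str(r["kappa_cdr3"]),
                "h_mut": _mutset(r["heavy_mutations"]), "k_mut": _mutset(r["kappa_mutations"]),
            }
            for _, r in grp.iterrows()
        ]
        # union-find over the clone/related relation
        parent = list(range(len(recs)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in itertools.combinations(range(len(recs)), 2):
            a, b = recs[i], recs[j]
            if not (
                _cdr3_compatible(a["h_cdr3"], b["h_cdr3"], require_cdr3_identity, min_cdr3_identity)
                and _cdr3_compatible(a["k_cdr3"], b["k_cdr3"], require_cdr3_identity, min_cdr3_identity)
            ):
                continue
            if _related(a["h_mut"], a["k_mut"], b["h_mut"], b["k_mut"]):
                parent[find(i)] = find(j)

        comps: dict[int, list[int]] = {}
        for i in range(len(recs)):
            comps.setdefault(find(i), []).append(i)

        for comp in sorted(comps.values(), key=lambda c: recs[c[0]]["id"]):
            if len(comp) < 2:
                continue
            shared_h = frozenset.intersection(*(recs[i]["h_mut"] for i in comp))
            shared_k = frozenset.intersection(*(recs[i]["k_mut"] for i in comp))
            n_minimal = sum(
                1 for i in comp
                if recs[i]["h_mut"] == shared_h and recs[i]["k_mut"] == shared_k
            )
            members = []
            for i in sorted(comp, key=lambda i: recs[i]["id"]):
                r = recs[i]
                minimal = r["h_mut"] == shared_h and r["k_mut"] == shared_k
                status = "identical-clone" if (minimal and n_minimal >= 2) else "clonally-related"
                members.append(CloneMember(
                    id=r["id"], status=status,
                    extra_heavy=len(r["h_mut"] - shared_h),
                    extra_kappa=len(r["k_mut"] - shared_k),
                ))
            rep = recs[comp[0]]
            cs = CloneSet(
                set_id=f"CS{len(sets) + 1}",
                heavy_v=grp.iloc[0]["heavy_v"], kappa_v=grp.iloc[0]["kappa_v"],
                heavy_cdr3=rep["h_cdr3"], kappa_cdr3=rep["k_cdr3"],
                isotype=str(grp.iloc[0]["isotype"]), members=members,
            )
            sets.append(cs)
            for m in members:
                rows.append({
                    "set_id": cs.set_id, "id": m.id, "status": m.status,
                    "heavy_v": cs.heavy_v, "kappa_v": cs.kappa_v,
                    "heavy_cdr3": cs.heavy_cdr3, "kappa_cdr3": cs.kappa_cdr3,
                    "isotype": cs.isotype,
                    "extra_heavy_mutations": m.extra_heavy,
                    "extra_kappa_mutations": m.extra_kappa,
                })
    membership = pd.DataFrame(
        rows, columns=["set_id", "id", "status", "heavy_v", "kappa_v", "heavy_cdr3",
                       "kappa_cdr3", "isotype", "extra_heavy_mutations",
                       "extra_kappa_mutations"])
    return sets, membership


def flag_related(cloneset: CloneSet) -> dict[str, tuple[str, int, int]]:
    """Per-member status and extra-mutation counts (heavy, kappa).

    Extra mutations are those beyond the intersection of all members'
    mutation sets — the lineage's shared footprint.
    """
    return {m.id: (m.status, m.extra_heavy, m.extra_kappa) for m in cloneset.members}


def oligoclonality(
    clonesets: list[CloneSet],
    stratum_of: pd.DataFrame,
    denominators: pd.Series | dict,
    *,
    strata_cols: tuple[str, ...] = ("strain", "age_weeks", "isotype"),
) -> pd.DataFrame:
    """Per-stratum oligoclonality: expanded-set count, expanded fraction, largest set.

    ``stratum_of`` maps id -> stratum columns; ``denominators`` gives the
    number of tested/analyzed records per stratum key (tuple over
    ``strata_cols``).  Strata with a zero denominator are flagged undefined.
    """
    meta = stratum_of.set_index("id")
    per_stratum: dict[tuple, dict] = {}
    for cs in clonesets:
        for m in cs.members:
            key = tuple(meta.loc[m.id][list(strata_cols)])
            entry = per_stratum.setdefault(
                key, {"n_sets": set(), "n_members": 0, "largest": 0})
            entry["n_sets"].add(cs.set_id)
            entry["n_members"] += 1
            entry["largest"] = max(entry["largest"], len(cs))
    denominators = dict(denominators)
    keys = set(per_stratum) | set(denominators)
    rows = []
    for key in sorted(keys, key=str):
        entry = per_stratum.get(key, {"n_sets": set(), "n_members": 0, "largest": 0})
        denom = int(denominators.get(key, 0))
        rows.append({
            **dict(zip(strata_cols, key)),
            "n_clone_sets": len(entry["n_sets"]),
            "n_expanded_members": entry["n_members"],
            "largest_set_size": entry["largest"],
            "denominator": denom,
            "expanded_fraction": entry["n_members"] / denom if denom else float("nan"),
            "defined": denom > 0,
        })
    return pd.DataFrame(rows)
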