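"""Synthetic hybridoma-repertoire simulator with known ground truth.

Generates libraries of monoclonal-antibody records with the statistical
structure the downstream analysis assumes: V(D)J recombination with
junctional diversity (exonuclease trimming, non-templated N insertions),
age-scaled somatic hypermutation confined to the V region, clonal expansion
of a few lineages (identical copies plus members carrying extra mutations),
and latent per-antigen binding strengths emitted as noisy ELISA optical
densities.  Every record carries a :class:`LatentTruth` so that gene
assignment, CDR3 extraction, mutation counting, reactivity classification
and clone grouping can all be checked against construction.

Two strain presets are provided: an autoimmune-prone profile whose
autoreactive/polyreactive IgG fractions rise with age and whose polyreactive
IgGs skew to IgG2b/IgG2c, and a control profile with low, flat prevalences
dominated by IgG3 — mirroring the contrast between a Sjögren's-like mouse
strain and wild-type C57BL/6J animals.

All randomness flows from a single integer seed per configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from polyrep.germline import HEAVY, KAPPA, GermlineReference, Segment

ANTIGENS = ("dsDNA", "H1", "Ro52", "LPS", "Insulin", "OVA")
_NT = np.array(list("ACGT"))


class SimulationError(ValueError):
    """Raised for invalid simulator configurations."""


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimulationConfig:
    """Parameters of one simulated library (one strain x one age).

    Prevalences are fractions of the library; ``polyreactive_frac`` +
    ``reactive_frac`` must not exceed 1, the remainder is non-reactive.
    ``shm_rate_per_nt`` is the expected number of point mutations per
    mutable V-region nucleotide; isotype multipliers rescale it so that
    class-switched IgG records carry more mutations than IgM.
    """

    strain: str = "NOD.H-2h4"
    age_weeks: int = 28
    library_size: int = 56
    seed: int = 0

    isotype_probs: dict[str, float] = field(default_factory=lambda: {"IgM": 0.5, "IgG": 0.5})
    subclass_probs: dict[str, float] = field(
        default_factory=lambda: {"IgG1": 0.12, "IgG2b": 0.55, "IgG2c": 0.25, "IgG3": 0.08}
    )
    polyreactive_frac: float = 0.25
    reactive_frac: float = 0.25
    ro52_given_poly: float = 0.3
    autoreactive_frac: float = 0.30

    shm_rate_per_nt: float = 0.004
    shm_isotype_mult: dict[str, float] = field(default_factory=lambda: {"IgM": 0.6, "IgG": 1.4})
    hotspot_weight: float = 1.0  # 1.0 = uniform; >1 concentrates at WRC/GYW motifs

    # junctional diversity (means of geometric trims / Poisson N-insertions)
    v_trim_mean: float = 2.0
    d_trim_mean: float = 2.0
    j_trim_mean: float = 2.0
    n_ins_mean_heavy: float = 3.0
    n_ins_mean_kappa: float = 1.0
    fraction_productive: float = 1.0
    ns_fraction: float = 0.03  # chains lost to failed sequencing ("NS")

    # clonal expansion
    n_expanded_lineages: int = 0
    lineage_sizes: tuple[int, ...] = ()
    p_extra_mutations: float = 0.0
    extra_members_per_lineage: tuple[int, ...] = ()  # overrides p_extra_mutations
    extra_heavy_mutations: int = 3
    extra_kappa_mutations: int = 2

    # ELISA emission
    binding_low: float = 0.8
    binding_high: float = 4.0
    strength_scale: float = 1.0
    od_max: float = 2.5
    od_halfsat: float = 1.0
    od_noise_sigma: float = 0.15
    bg_mean: float = 0.05
    bg_sd: float = 0.01
    n_blanks: int = 8

    def validate(self) -> None:
        for name in ("polyreactive_frac", "reactive_frac", "ro52_given_poly",
                     "autoreactive_frac", "fraction_productive", "ns_fraction",
                     "p_extra_mutations"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0, 1]")
        if self.polyreactive_frac + self.reactive_frac > 1.0 + 1e-9:
            raise SimulationError("polyreactive_frac + reactive_frac exceed 1")
        for probs in (self.isotype_probs, self.subclass_probs):
            if abs(sum(probs.values()) - 1.0) > 1e-6:
                raise SimulationError(f"probability vector {probs} does not sum to 1")
        if self.shm_rate_per_nt < 0:
            raise SimulationError("shm_rate_per_nt must be >= 0")
        if self.n_expanded_lineages != len(self.lineage_sizes):
            raise SimulationError("lineage_sizes must list one size per expanded lineage")
        if any(s < 2 for s in self.lineage_sizes):
            raise SimulationError("lineage sizes must be >= 2")
        if self.extra_members_per_lineage:
            if len(self.extra_members_per_lineage) != len(self.lineage_sizes):
                raise SimulationError("extra_members_per_lineage must match lineage_sizes")
            if any(e > s - 1 for e, s in zip(self.extra_members_per_lineage,
                                            self.lineage_sizes)):
                raise SimulationError("more extra-mutation members than lineage copies")
        if sum(s - 1 for s in self.lineage_sizes) >= self.library_size:
            raise SimulationError("requested lineage members exceed library size")


_SJS_PREVALENCE = {
    # age_weeks: (polyreactive, reactive, autoreactive, ro52 | polyreactive)
    28: (0.25, 0.25, 0.30, 0.30),
    47: (0.35, 0.25, 0.45, 0.55),
    66: (0.55, 0.25, 0.61, 0.85),
}
_B6_PREVALENCE = {
    26: (0.10, 0.20, 0.15, 0.10),
    47: (0.12, 0.20, 0.18, 0.10),
    69: (0.15, 0.20, 0.22, 0.10),
}
_SHM_RATE_PER_WEEK = 1.3e-4  # per mutable nt; ~2.4 expected nt mutations at 66 w


def sjs_preset(age_weeks: int = 66, library_size: int = 56, seed: int = 0,
               **overrides) -> SimulationConfig:
    """Autoimmune-prone (Sjögren's-like) strain preset at one age point."""
    if age_weeks not in _SJS_PREVALENCE:
        raise SimulationError(f"no SjS preset for age {age_weeks}; ages: 28, 47, 66")
    poly, reac, auto, ro52 = _SJS_PREVALENCE[age_weeks]
    cfg = SimulationConfig(
        strain="NOD.H-2h4", age_weeks=age_weeks, library_size=library_size, seed=seed,
        polyreactive_frac=poly, reactive_frac=reac, autoreactive_frac=auto,
        ro52_given_poly=ro52,
        shm_rate_per_nt=_SHM_RATE_PER_WEEK * age_weeks,
        strength_scale=1.0 + 0.01 * max(age_weeks - 28, 0),
        subclass_probs={"IgG1": 0.12, "IgG2b": 0.55, "IgG2c": 0.25, "IgG3": 0.08},
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


def b6_preset(age_weeks: int = 69, library_size: int = 62, seed: int = 0,
              **overrides) -> SimulationConfig:
    """Control (C57BL/6J-like) strain preset at one age point."""
    if age_weeks not in _B6_PREVALENCE:
        raise SimulationError(f"no B6 preset for age {age_weeks}; ages: 26, 47, 69")
    poly, reac, auto, ro52 = _B6_PREVALENCE[age_weeks]
    cfg = SimulationConfig(
        strain="C57BL/6J", age_weeks=age_weeks, library_size=library_size, seed=seed,
        polyreactive_frac=poly, reactive_frac=reac, autoreactive_frac=auto,
        ro52_given_poly=ro52,
        shm_rate_per_nt=_SHM_RATE_PER_WEEK * age_weeks,
        subclass_probs={"IgG1": 0.25, "IgG2b": 0.15, "IgG2c": 0.10, "IgG3": 0.50},
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# truth containers


@dataclass
class ChainTruth:
    """Ground truth for one rearranged chain."""

    v_gene: str
    d_gene: str | None  # None for kappa, or when the surviving D core is < 5 nt
    j_gene: str
    seq: str
    cdr3_aa: str | None
    junction_nt: str
    productive: bool
    mutations: list[tuple[int, str, str]] = field(default_factory=list)


@dataclass
class LatentTruth:
    category: str  # non-reactive | reactive | polyreactive
    ro52: bool
    autoreactive: bool
    binding: dict[str, float] = field(default_factory=dict)
    clone_id: str | None = None
    clone_role: str | None = None  # founder | identical | related
    heavy: ChainTruth | None = None
    kappa: ChainTruth | None = None


@dataclass
class HybridomaRecord:
    id: str
    strain: str
    age_weeks: int
    isotype: str
    subclass: str  # "" for IgM
    truth: LatentTruth

    @property
    def heavy_seq(self) -> str | None:
        return self.truth.heavy.seq if self.truth.heavy else None

    @property
    def kappa_seq(self) -> str | None:
        return self.truth.kappa.seq if self.truth.kappa else None


@dataclass
class HybridomaLibrary:
    records: list[HybridomaRecord]
    config: SimulationConfig | None = None

    def __len__(self) -> int:
        return len(self.records)

    # -- tidy views ---------------------------------------------------------

    def metadata_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "id": r.id, "strain": r.strain, "age_weeks": r.age_weeks,
                "isotype": r.isotype, "subclass": r.subclass,
                "autoreactive_flag": int(r.truth.autoreactive),
            })
        return pd.DataFrame(rows, columns=["id", "strain", "age_weeks", "isotype",
                                           "subclass", "autoreactive_flag"])

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "id": r.id,
                "category": r.truth.category,
                "ro52": int(r.truth.ro52),
                "autoreactive": int(r.truth.autoreactive),
                "clone_id": r.truth.clone_id or "",
                "clone_role": r.truth.clone_role or "",
            }
            for ag in ANTIGENS:
                row[f"binding_{ag}"] = r.truth.binding.get(ag, 0.0)
            for chain_name, ct in (("heavy", r.truth.heavy), ("kappa", r.truth.kappa)):
                row[f"{chain_name}_v"] = ct.v_gene if ct else ""
                row[f"{chain_name}_d"] = (ct.d_gene or "") if ct else ""
                row[f"{chain_name}_j"] = ct.j_gene if ct else ""
                row[f"{chain_name}_cdr3"] = (ct.cdr3_aa or "") if ct else ""
                row[f"{chain_name}_productive"] = int(ct.productive) if ct else 0
                row[f"{chain_name}_mutations"] = serialize_mutations(ct.mutations) if ct else ""
            rows.append(row)
        return pd.DataFrame(rows)


def serialize_mutations(muts: Sequence[tuple[int, str, str]]) -> str:
    return ";".join(f"{p}:{a}>{b}" for p, a, b in sorted(muts))


def parse_mutations(text: str) -> list[tuple[int, str, str]]:
    if not text or (isinstance(text, float) and np.isnan(text)):
        return []
    out = []
    for tok in str(text).split(";"):
        pos, rest = tok.split(":")
        a, b = rest.split(">")
        out.append((int(pos), a, b))
    return out


# ---------------------------------------------------------------------------
# recombination


def _geom_trim(rng: np.random.Generator, mean: float, cap: int) -> int:
    if mean <= 0:
        return 0
    draw = rng.geometric(1.0 / (1.0 + mean)) - 1
    return int(min(draw, cap))


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=n)])


def _lcs_len(a: str, b: str) -> int:
    """Length of the longest common substring (simple DP; inputs are short)."""
    best = 0
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        ai = a[i - 1]
        for j in range(1, len(b) + 1):
            if ai == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def _has_stop(nt: str) -> bool:
    n = len(nt) - len(nt) % 3
    return "*" in str(Seq(nt[:n]).translate())


def recombine(
    reference: GermlineReference,
    locus: str,
    rng: np.random.Generator,
    *,
    v_trim_mean: float = 2.0,
    d_trim_mean: float = 2.0,
    j_trim_mean: float = 2.0,
    n_ins_mean: float = 3.0,
    force_productive: bool = True,
    max_attempts: int = 500,
) -> ChainTruth:
    """Simulate one V(D)J rearrangement at the given locus.

    The emitted sequence is V[3'-trimmed] + N + (D[trimmed] + N, heavy only)
    + J[5'-trimmed], with the V reading frame preserved at the 5' end.  When
    ``force_productive`` the junction is redrawn until it is in-frame with no
    stop codon.  Junctions are additionally redrawn until the surviving D
    core is unambiguously attributable (no competing D gene shares an equal
    or longer substring of the junction), which keeps the latent D label
    well-defined; fully trimmed D segments are recorded as ``None``.
    """
    v_pool = reference.segments(locus, "V")
    j_pool = reference.segments(locus, "J")
    d_pool = reference.segments(locus, "D") if locus == HEAVY else []
    if not v_pool or not j_pool or (locus == HEAVY and not d_pool):
        raise SimulationError(f"empty segment pool for locus {locus!r}")

    v: Segment = v_pool[rng.integers(len(v_pool))]
    j: Segment = j_pool[rng.integers(len(j_pool))]
    d: Segment | None = d_pool[rng.integers(len(d_pool))] if locus == HEAVY else None

    cys_end = v.regions["fr3_end"]
    v_tail = len(v.seq) - cys_end  # germline nt available 3' of the 2nd-Cys
    j_pre = j.anchor_start  # nt of J 5' of its anchor codon

    last = None
    for attempt in range(max_attempts):
        v_trim = _geom_trim(rng, v_trim_mean, v_tail)
        j_trim = _geom_trim(rng, j_trim_mean, j_pre)
        if d is not None:
            d5 = _geom_trim(rng, d_trim_mean, len(d.seq))
            d3 = _geom_trim(rng, d_trim_mean, len(d.seq) - d5)
            d_core = d.seq[d5 : len(d.seq) - d3]
            n1 = _random_nt(rng, rng.poisson(n_ins_mean))
            n2 = _random_nt(rng, rng.poisson(n_ins_mean))
            junction_insert = n1 + d_core + n2
        else:
            d_core = ""
            junction_insert = _random_nt(rng, rng.poisson(n_ins_mean))

        seq = v.seq[: len(v.seq) - v_trim] + junction_insert + j.seq[j_trim:]
        j_anchor_q = len(v.seq) - v_trim + len(junction_insert) + (j_pre - j_trim)
        in_frame = (j_anchor_q - cys_end) % 3 == 0
        productive = in_frame and not _has_stop(seq)

        if d is not None:
            # identifiability of the latent D label (see docstring); the
            # region between the anchors is what the annotator searches
            region = seq[cys_end:j_anchor_q]
            true_len = _lcs_len(region, d.seq)
            observable = len(d_core) >= 5
            competing = max(
                (_lcs_len(region, other.seq) for other in d_pool if other.name != d.name),
                default=0,
            )
            if observable and competing >= max(true_len, 5):
                continue
            if not observable and max(competing, true_len) >= 5:
                continue
            d_label = d.name if observable else None
        else:
            d_label = None

        cdr3_aa = None
        if in_frame and cys_end <= j_anchor_q:
            cdr3_nt = seq[cys_end:j_anchor_q]
            cdr3_aa = str(Seq(cdr3_nt).translate()) if len(cdr3_nt) % 3 == 0 else None
            if cdr3_aa is not None and "*" in cdr3_aa:
                cdr3_aa = None

        junction_nt = seq[cys_end - 3 : j_anchor_q + 3]
        last = ChainTruth(v.name, d_label, j.name, seq, cdr3_aa, junction_nt, productive)
        if not force_productive or productive:
            return last
    if last is None:
        raise SimulationError("recombination failed to produce a junction")
    return last  # give up forcing productivity after max_attempts


# ---------------------------------------------------------------------------
# somatic hypermutation


def _hotspot_weights(seq: str, weight: float) -> np.ndarray:
    """Per-site sampling weights; WRC/GYW AID hotspot positions get `weight`."""
    w = np.ones(len(seq))
    if weight == 1.0:
        return w
    s = seq.upper()
    for i in range(len(s) - 2):
        tri = s[i : i + 3]
        if tri[0] in "AT" and tri[1] in "AG" and tri[2] == "C":  # WRC, mutates the C
            w[i + 2] = weight
        if tri[0] == "G" and tri[1] in "CT" and tri[2] in "AT":  # GYW, mutates the G
            w[i] = weight
    return w


def mutate(
    sequence: str,
    rate: float,
    rng: np.random.Generator,
    *,
    mutable_start: int = 0,
    mutable_end: int | None = None,
    hotspot_weight: float = 1.0,
    forbid_stops_through: int | None = None,
    existing: Sequence[int] = (),
    exact_count: int | None = None,
    max_attempts: int = 200,
) -> tuple[str, list[tuple[int, str, str]]]:
    """Introduce point mutations into ``sequence``.

    The mutation count is Poisson(rate x mutable length) unless
    ``exact_count`` is given.  Mutations fall on distinct positions in
    ``[0, mutable_end)`` not listed in ``existing``; when
    ``forbid_stops_through`` is set, draws creating a stop codon in the
    frame-0 translation of that prefix are rejected and redrawn.
    """
    if rate < 0:
        raise SimulationError("mutation rate must be >= 0")
    end = len(sequence) if mutable_end is None else mutable_end
    if exact_count is None:
        n = int(rng.poisson(rate * end))
    else:
        n = exact_count
    if n == 0:
        return sequence, []
    candidates = np.array([i for i in range(mutable_start, end) if i not in set(existing)])
    if n > len(candidates):
        n = len(candidates)
    weights = _hotspot_weights(sequence[:end], hotspot_weight)[candidates]
    weights = weights / weights.sum()
    for _ in range(max_attempts):
        pos = rng.choice(candidates, size=n, replace=False, p=weights)
        seq = list(sequence)
        muts = []
        for p in sorted(int(x) for x in pos):
            old = seq[p]
            new = [b for b in "ACGT" if b != old][rng.integers(0, 3)]
            seq[p] = new
            muts.append((p, old, new))
        mutated = "".join(seq)
        if forbid_stops_through is not None and _has_stop(mutated[:forbid_stops_through]):
            continue
        return mutated, muts
    return sequence, []  # could not place mutations without a stop; leave germline


# ---------------------------------------------------------------------------
# library assembly


def _sample_category(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[str, bool]:
    u = rng.random()
    if u < cfg.polyreactive_frac:
        return "polyreactive", rng.random() < cfg.ro52_given_poly
    if u < cfg.polyreactive_frac + cfg.reactive_frac:
        return "reactive", False  # anti-Ro52 clones are polyreactive by construction
    return "non-reactive", False


def _sample_binding(cfg: SimulationConfig, category: str, ro52: bool,
                    rng: np.random.Generator) -> dict[str, float]:
    binding = {ag: 0.0 for ag in ANTIGENS}
    if category == "non-reactive":
        return binding
    if category == "polyreactive":
        k = int(rng.integers(3, len(ANTIGENS) + 1))
    else:
        k = int(rng.integers(1, 3))
    pool = [ag for ag in ANTIGENS if ag != "Ro52"]
    chosen = list(rng.choice(pool, size=min(k, len(pool)), replace=False))
    if ro52:
        chosen = ["Ro52"] + chosen[: k - 1]
    for ag in chosen[:k]:
        binding[ag] = float(rng.uniform(cfg.binding_low, cfg.binding_high) * cfg.strength_scale)
    return binding


def _simulate_record(cfg: SimulationConfig, reference: GermlineReference,
                     rng: np.random.Generator, rec_id: str) -> HybridomaRecord:
    isotypes = sorted(cfg.isotype_probs)
    iso = str(rng.choice(isotypes, p=[cfg.isotype_probs[i] for i in isotypes]))
    if iso == "IgG":
        subs = sorted(cfg.subclass_probs)
        subclass = str(rng.choice(subs, p=[cfg.subclass_probs[s] for s in subs]))
    else:
        subclass = ""

    category, ro52 = _sample_category(cfg, rng)
    autoreactive = category == "polyreactive"
    if not autoreactive and cfg.autoreactive_frac > cfg.polyreactive_frac:
        p_extra = (cfg.autoreactive_frac - cfg.polyreactive_frac) / max(
            1.0 - cfg.polyreactive_frac, 1e-9)
        autoreactive = rng.random() < p_extra
    binding = _sample_binding(cfg, category, ro52, rng)

    chains: dict[str, ChainTruth | None] = {}
    for locus, n_ins in ((HEAVY, cfg.n_ins_mean_heavy), (KAPPA, cfg.n_ins_mean_kappa)):
        if rng.random() < cfg.ns_fraction:
            chains[locus] = None  # sequencing failed: "NS" in reports
            continue
        force = rng.random() < cfg.fraction_productive
        ct = recombine(
            reference, locus, rng,
            v_trim_mean=cfg.v_trim_mean, d_trim_mean=cfg.d_trim_mean,
            j_trim_mean=cfg.j_trim_mean, n_ins_mean=n_ins, force_productive=force,
        )
        if cfg.shm_rate_per_nt > 0:
            v = reference.get(locus, "V", ct.v_gene)
            cys_start = v.regions["fr3_end"] - 3
            rate = cfg.shm_rate_per_nt * cfg.shm_isotype_mult.get(iso, 1.0)
            # position 0 is excluded: a mismatch at the extreme 5' terminus is
            # always clipped by local alignment, hence unrecoverable downstream
            seq, muts = mutate(
                ct.seq, rate, rng, mutable_start=1, mutable_end=cys_start,
                hotspot_weight=cfg.hotspot_weight,
                forbid_stops_through=v.regions["fr3_end"],
            )
            ct.seq, ct.mutations = seq, muts
        chains[locus] = ct

    truth = LatentTruth(category=category, ro52=ro52, autoreactive=autoreactive,
                        binding=binding, heavy=chains[HEAVY], kappa=chains[KAPPA])
    return HybridomaRecord(rec_id, cfg.strain, cfg.age_weeks, iso, subclass, truth)


def expand_clones(
    library: HybridomaLibrary,
    reference: GermlineReference,
    rng: np.random.Generator,
    *,
    lineage_sizes: Sequence[int],
    p_extra_mutations: float = 0.0,
    extra_members_per_lineage: Sequence[int] | None = None,
    extra_heavy_mutations: int = 3,
    extra_kappa_mutations: int = 2,
) -> HybridomaLibrary:
    """Duplicate founder records into clonal lineages.

    Members are exact copies of the founder (identical sequences and
    mutation sets on both chains) except that some acquire a fixed number of
    additional V-region mutations per chain — the signature of further
    rounds of antigen-driven hypermutation within a lineage.  Extra-mutation
    members are chosen per copy with probability ``p_extra_mutations``, or
    deterministically (the last N copies of each lineage) when
    ``extra_members_per_lineage`` is given.  Founders are drawn from
    productive, paired, polyreactive IgG records (falling back to any paired
    productive record), since expanded lineages are an IgG phenomenon here.
    """
    if not library.records:
        raise SimulationError("cannot expand an empty library")
    if not lineage_sizes:
        return library

    def paired_productive(r: HybridomaRecord) -> bool:
        return (r.truth.heavy is not None and r.truth.kappa is not None
                and r.truth.heavy.productive and r.truth.kappa.productive)

    pool = [r for r in library.records
            if paired_productive(r) and r.isotype == "IgG"
            and r.truth.category == "polyreactive" and r.truth.clone_id is None]
    if len(pool) < len(lineage_sizes):
        pool = [r for r in library.records if paired_productive(r) and r.truth.clone_id is None]
    if len(pool) < len(lineage_sizes):
        raise SimulationError("not enough eligible founders for the requested lineages")

    founders = rng.choice(len(pool), size=len(lineage_sizes), replace=False)
    new_records: list[HybridomaRecord] = []
    for li, (fi, size) in enumerate(zip(founders, lineage_sizes)):
        founder = pool[int(fi)]
        clone_id = f"{founder.strain}.{founder.age_weeks}w.L{li + 1}"
        founder.truth.clone_id = clone_id
        founder.truth.clone_role = "founder"
        for m in range(size - 1):
            copy = HybridomaRecord(
                id=f"{founder.id}c{m + 1}", strain=founder.strain,
                age_weeks=founder.age_weeks, isotype=founder.isotype,
                subclass=founder.subclass,
                truth=LatentTruth(
                    category=founder.truth.category, ro52=founder.truth.ro52,
                    autoreactive=founder.truth.autoreactive,
                    binding=dict(founder.truth.binding), clone_id=clone_id,
                    clone_role="identical",
                    heavy=dataclasses.replace(founder.truth.heavy,
                                              mutations=list(founder.truth.heavy.mutations)),
                    kappa=dataclasses.replace(founder.truth.kappa,
                                              mutations=list(founder.truth.kappa.mutations)),
                ),
            )
            if extra_members_per_lineage is not None:
                gets_extra = m >= (size - 1) - extra_members_per_lineage[li]
            else:
                gets_extra = rng.random() < p_extra_mutations
            if gets_extra:
                copy.truth.clone_role = "related"
                for locus, n_extra in ((HEAVY, extra_heavy_mutations),
                                       (KAPPA, extra_kappa_mutations)):
                    ct = copy.truth.heavy if locus == HEAVY else copy.truth.kappa
                    v = reference.get(locus, "V", ct.v_gene)
                    seq, extra = mutate(
                        ct.seq, 0.0, rng, mutable_start=1,
                        mutable_end=v.regions["fr3_end"] - 3,
                        forbid_stops_through=v.regions["fr3_end"],
                        existing=[p for p, _, _ in ct.mutations],
                        exact_count=n_extra,
                    )
                    ct.seq = seq
                    ct.mutations = ct.mutations + extra
                # extra mutations raise reactivity strength (affinity maturation)
                copy.truth.binding = {ag: b * 2.5 if b > 0 else 0.0
                                      for ag, b in copy.truth.binding.items()}
            new_records.append(copy)
    return HybridomaLibrary(library.records + new_records, library.config)


def simulate_library(cfg: SimulationConfig,
                     reference: GermlineReference | None = None) -> HybridomaLibrary:
    """Simulate one library of ``cfg.library_size`` records (lineages included)."""
    cfg.validate()
    if reference is None:
        from polyrep.germline import load_default_germline

        reference = load_default_germline()
    rng = np.random.default_rng(cfg.seed)
    n_extra = sum(s - 1 for s in cfg.lineage_sizes)
    base_n = cfg.library_size - n_extra
    prefix = f"{'SJS' if 'NOD' in cfg.strain else 'B6'}.{cfg.age_weeks}w"
    records = [_simulate_record(cfg, reference, rng, f"{prefix}.{i + 1}")
               for i in range(base_n)]
    lib = HybridomaLibrary(records, cfg)
    if cfg.lineage_sizes:
        lib = expand_clones(
            lib, reference, rng, lineage_sizes=cfg.lineage_sizes,
            p_extra_mutations=cfg.p_extra_mutations,
            extra_members_per_lineage=cfg.extra_members_per_lineage or None,
            extra_heavy_mutations=cfg.extra_heavy_mutations,
            extra_kappa_mutations=cfg.extra_kappa_mutations,
        )
    return lib


def simulate_study(seed: int = 0, *, sjs_size: int = 56, b6_size: int = 62,
                   reference: GermlineReference | None = None) -> HybridomaLibrary:
    """Simulate the full two-strain, three-age study design.

    Three age points per strain; the oldest autoimmune-prone cohort carries
    two expanded IgG lineages (sizes 2 and 3, one member of the larger
    lineage with extra mutations), matching the oligoclonality structure the
    analysis is meant to detect.  Library sizes default to 3 x 56 = 168
    autoimmune-prone and 3 x 62 = 186 control records.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
    libs: list[HybridomaLibrary] = []
    for i, age in enumerate((28, 47, 66)):
        overrides = {}
        if age == 66:
            overrides = dict(n_expanded_lineages=2, lineage_sizes=(2, 3),
                             extra_members_per_lineage=(0, 1))
        libs.append(simulate_library(
            sjs_preset(age, library_size=sjs_size, seed=seeds[i], **overrides),
            reference))
    for i, age in enumerate((26, 47, 69)):
        libs.append(simulate_library(
            b6_preset(age, library_size=b6_size, seed=seeds[3 + i]), reference))
    return HybridomaLibrary([r for lib in libs for r in lib.records])


# ---------------------------------------------------------------------------
# ELISA emission and file round trip


def emit_reactivity(library: HybridomaLibrary, rng: np.random.Generator | None = None,
                    *, od_max: float | None = None, od_halfsat: float | None = None,
                    noise_sigma: float | None = None, bg_mean: float | None = None,
                    bg_sd: float | None = None, n_blanks: int | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit a tidy OD table and blank wells from latent binding strengths.

    OD = od_max * b / (b + halfsat) * exp(N(0, sigma)) + N(bg_mean, bg_sd),
    i.e. a saturating binding curve with multiplicative log-normal noise on
    the specific signal and additive plate background.  Returns
    ``(meta_od, blanks)`` data frames.
    """
    cfg = library.config or SimulationConfig()
    od_max = cfg.od_max if od_max is None else od_max
    halfsat = cfg.od_halfsat if od_halfsat is None else od_halfsat
    sigma = cfg.od_noise_sigma if noise_sigma is None else noise_sigma
    bg_mean = cfg.bg_mean if bg_mean is None else bg_mean
    bg_sd = cfg.bg_sd if bg_sd is None else bg_sd
    n_blanks = cfg.n_blanks if n_blanks is None else n_blanks
    if rng is None:
        rng = np.random.default_rng((cfg.seed + 1) % (2**31))

    meta = library.metadata_frame()
    for ag in ANTIGENS:
        b = np.array([r.truth.binding.get(ag, 0.0) for r in library.records])
        if (b < 0).any():
            raise SimulationError("binding strengths must be >= 0")
        signal = od_max * b / (b + halfsat)
        noise = np.exp(rng.normal(0.0, sigma, size=len(b))) if sigma > 0 else 1.0
        background = rng.normal(bg_mean, bg_sd, size=len(b)) if bg_sd > 0 else bg_mean
        meta[ag] = signal * noise + background
    blank_od = (rng.normal(bg_mean, bg_sd, size=n_blanks) if bg_sd > 0
                else np.full(n_blanks, bg_mean))
    blanks = pd.DataFrame({"well": [f"blank{i + 1}" for i in range(n_blanks)],
                           "od": blank_od})
    return meta, blanks


def write_library(library: HybridomaLibrary, outdir: str | Path,
                  rng: np.random.Generator | None = None) -> dict[str, Path]:
    """Write FASTA per chain plus metadata/OD, blanks and truth TSVs.

    Record ids in the FASTA are ``<hybridoma id>|<chain>``.  Reading the
    directory back with :func:`read_library` reproduces the library.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / v for k, v in (
        ("heavy_fasta", "heavy.fasta"), ("kappa_fasta", "kappa.fasta"),
        ("meta_od", "meta_od.tsv"), ("blanks", "blanks.tsv"), ("truth", "truth.tsv"),
    )}
    with open(paths["heavy_fasta"], "w") as fh, open(paths["kappa_fasta"], "w") as fk:
        for r in library.records:
            if r.heavy_seq:
                fh.write(f">{r.id}|heavy\n{r.heavy_seq}\n")
            if r.kappa_seq:
                fk.write(f">{r.id}|kappa\n{r.kappa_seq}\n")
    meta_od, blanks = emit_reactivity(library, rng)
    meta_od.to_csv(paths["meta_od"], sep="\t", index=False)
    blanks.to_csv(paths["blanks"], sep="\t", index=False)
    library.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths


def read_library(indir: str | Path) -> HybridomaLibrary:
    """Rebuild a :class:`HybridomaLibrary` from :func:`write_library` output."""
    from Bio import SeqIO

    indir = Path(indir)
    seqs: dict[tuple[str, str], str] = {}
    for chain in (HEAVY, KAPPA):
        path = indir / f"{chain}.fasta"
        if path.exists():
            for rec in SeqIO.parse(str(path), "fasta"):
                rid, _, ch = rec.id.rpartition("|")
                seqs[(rid, ch)] = str(rec.seq)
    meta = pd.read_csv(indir / "meta_od.tsv", sep="\t", dtype={"id": str},
                       keep_default_na=False)
    truth = pd.read_csv(indir / "truth.tsv", sep="\t", dtype={"id": str},
                        keep_default_na=False).set_index("id")
    records = []
    for _, row in meta.iterrows():
        t = truth.loc[row["id"]]
        chains: dict[str, ChainTruth | None] = {}
        for chain in (HEAVY, KAPPA):
            seq = seqs.get((row["id"], chain))
            if seq is None:
                chains[chain] = None
                continue
            chains[chain] = ChainTruth(
                v_gene=t[f"{chain}_v"], d_gene=t[f"{chain}_d"] or None,
                j_gene=str(t[f"{chain}_j"]), seq=seq,
                cdr3_aa=t[f"{chain}_cdr3"] or None,
                junction_nt="", productive=bool(int(t[f"{chain}_productive"])),
                mutations=parse_mutations(t[f"{chain}_mutations"]),
            )
        records.append(HybridomaRecord(
            id=row["id"], strain=row["strain"], age_weeks=int(row["age_weeks"]),
            isotype=row["isotype"], subclass=row["subclass"],
            truth=LatentTruth(
                category=t["category"], ro52=bool(int(t["ro52"])),
                autoreactive=bool(int(t["autoreactive"])),
                binding={ag: float(t[f"binding_{ag}"]) for ag in ANTIGENS},
                clone_id=t["clone_id"] or None, clone_role=t["clone_role"] or None,
                heavy=chains[HEAVY], kappa=chains[KAPPA],
            ),
        ))
    return HybridomaLibrary(records)
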