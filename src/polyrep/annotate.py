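"""Immunoglobulin V(D)J annotation: germline assignment, CDR3, mutations.

A desk-scale annotator in the spirit of IMGT/V-QUEST, operating against a
:class:`~polyrep.germline.GermlineReference`:

* V and J genes are assigned by best local alignment (match +2, mismatch -1,
  gap open -4, extend -1); heavy D genes by the longest ungapped match of at
  least 5 nt inside the junction.  Ties break on percent identity, then on
  lexicographic gene name, so annotation is deterministic.
* A rearrangement is *productive* when the junction is in-frame and the
  translated V-through-J region carries no stop codon.
* The CDR3 is the translation of the nucleotides strictly between the
  conserved V-region second cysteine (excluded) and the J-region
  tryptophan/phenylalanine anchor (excluded) — the convention in which
  heavy-chain CDR3 strings typically begin "AR".  The junction including
  both anchors is also reported.
* Somatic mutations are mismatches against the assigned germline V within
  the aligned span up to the end of FR3, tallied per region (FR1, CDR1, FR2,
  CDR2, FR3) and split into replacement vs silent at codon level: every
  mutation in a codon whose translation changed counts as replacement.
  CDR3/junction positions are not counted, since the junction has no
  germline to compare against.

Coordinates are 0-based half-open internally, 1-based in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from polyrep.germline import HEAVY, KAPPA, GermlineReference, Segment

NS = "NS"  # no sequence recovered for the chain
REGIONS = ("FR1", "CDR1", "FR2", "CDR2", "FR3")
MIN_QUERY_LEN = 100
MIN_V_SCORE = 80.0  # alignment-score floor below which a V call is refused
MIN_D_CORE = 5


class AnnotationError(ValueError):
    pass


def make_aligner(match: float = 2.0, mismatch: float = -1.0,
                 gap_open: float = -4.0, gap_extend: float = -1.0) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


@dataclass
class AlignmentResult:
    """Best local alignment of one germline segment against the query."""

    query_id: str
    gene: str
    score: float
    identity: float  # percent of aligned columns matching
    q_start: int
    q_end: int
    g_start: int
    g_end: int
    gaps: int
    blocks: tuple = ()  # ((q_start, q_end), (g_start, g_end)) aligned block pairs

    def map_to_query(self, g_pos: int) -> int | None:
        """Query position of germline position ``g_pos`` (None if uncovered)."""
        for (qs, qe), (gs, ge) in self.blocks:
            if gs <= g_pos < ge:
                return qs + (g_pos - gs)
        return None



def _align(aligner: PairwiseAligner, query: str, seg: Segment, query_id: str,
           offset: int = 0) -> AlignmentResult | None:
    if not query:
        return None
    aln = aligner.align(query, seg.seq)
    if len(aln) == 0:
        return None
    best = aln[0]
    qb, gb = best.aligned
    matches = sum(
        1
        for (qs, qe), (gs, ge) in zip(qb, gb)
        for i in range(qe - qs)
        if query[qs + i] == seg.seq[gs + i]
    )
    cols = sum(qe - qs for qs, qe in qb)
    gaps = (qb[-1][1] - qb[0][0]) - cols + (gb[-1][1] - gb[0][0]) - cols
    blocks = tuple(((qs + offset, qe + offset), (gs, ge)) for (qs, qe), (gs, ge) in zip(qb, gb))
    return AlignmentResult(
        query_id=query_id, gene=seg.name, score=float(best.score),
        identity=100.0 * matches / cols if cols else 0.0,
        q_start=int(qb[0][0]) + offset, q_end=int(qb[-1][1]) + offset,
        g_start=int(gb[0][0]), g_end=int(gb[-1][1]), gaps=int(gaps), blocks=blocks,
    )


def _best(results: Iterable[AlignmentResult | None]) -> AlignmentResult | None:
    pool = [r for r in results if r is not None]
    if not pool:
        return None
    return min(pool, key=lambda r: (-r.score, -r.identity, r.gene))


def _best_by_score(aligner: PairwiseAligner, query: str, segments: list[Segment],
                   query_id: str, offset: int = 0) -> AlignmentResult | None:
    """Best segment by score; full alignments computed only for the top ties."""
    if not query:
        return None
    scores = [float(aligner.score(query, seg.seq)) for seg in segments]
    top = max(scores)
    tied = [seg for seg, s in zip(segments, scores) if s == top]
    return _best(_align(aligner, query, seg, query_id, offset) for seg in tied)


def _longest_common_substring(a: str, b: str) -> tuple[int, int, int]:
    """(length, start_in_a, start_in_b) of the longest exact shared substring."""
    best = (0, 0, 0)
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        ai = a[i - 1]
        for j in range(1, len(b) + 1):
            if ai == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best[0]:
                    best = (cur[j], i - cur[j], j - cur[j])
        prev = cur
    return best


def locate_anchor(sequence: str, res: AlignmentResult, seg: Segment) -> int | None:
    """Query position of a segment's anchor codon, validated by residue.

    The anchor is projected linearly from each aligned block (longest first):
    optimal local alignments routinely misbehave right at the junction —
    clipping a few terminal germline positions, or paying a gap to match
    junction nucleotides against the germline tail — so the long,
    framework-anchored block is the trustworthy frame of reference.  A
    candidate position is accepted only when its codon translates to the
    germline anchor residue; a mutated or junction-destroyed anchor leaves
    the CDR3 undefined rather than silently wrong.
    """
    if seg.anchor_start is None or not res.blocks:
        return None
    expected = str(Seq(seg.anchor_codon()).translate())
    blocks = sorted(res.blocks, key=lambda b: b[0][1] - b[0][0], reverse=True)
    for (qs, _), (gs, _) in blocks:
        q = qs + (seg.anchor_start - gs)
        if q < 0 or q + 3 > len(sequence):
            continue
        if str(Seq(sequence[q : q + 3]).translate()) == expected:
            return q
    return None


@dataclass
class ChainAnnotation:
    """Full annotation of one sequenced chain."""

    id: str
    chain: str
    v_gene: str | None = None
    d_gene: str | None = None
    j_gene: str | None = None
    productive: bool = False
    reason: str = ""  # why non-productive / unannotatable
    junction_nt: str = ""
    cdr3_aa: str | None = None
    cdr3_length: int | None = None
    v_identity: float | None = None
    mutations: list[tuple[int, str, str]] = field(default_factory=list)
    region_tallies: dict[str, int] = field(default_factory=lambda: {r: 0 for r in REGIONS})
    nt_replacement: int = 0
    nt_silent: int = 0
    aa_replacements: int = 0
    alignments: dict[str, AlignmentResult] = field(default_factory=dict)


def assign_segments(
    sequence: str,
    reference: GermlineReference,
    chain: str,
    *,
    aligner: PairwiseAligner | None = None,
    query_id: str = "query",
) -> dict[str, AlignmentResult]:
    """Assign V, J and (heavy) D segments by alignment.

    V: best local-alignment score over all V segments.  J: best score on the
    query region 3' of the V match.  D: longest ungapped exact match >= 5 nt
    between the V and J matches (absent when none qualifies).
    """
    if len(sequence) < MIN_QUERY_LEN:
        raise AnnotationError(f"{query_id}: query shorter than {MIN_QUERY_LEN} nt")
    if not reference.segments(chain, "V"):
        raise AnnotationError(f"germline reference has no {chain} V segments")
    aligner = aligner or make_aligner()
    sequence = sequence.upper()

    v_res = _best_by_score(aligner, sequence, reference.segments(chain, "V"), query_id)
    if v_res is None or v_res.score < MIN_V_SCORE:
        raise AnnotationError(f"{query_id}: no V alignment above score floor")
    out = {"V": v_res}

    # search J 3' of the V's 2nd-Cys anchor: the V local alignment can extend
    # a considerable distance into the junction on chance matches against the
    # germline V tail, truncating the region left for the true J
    v_seg = reference.get(chain, "V", v_res.gene)
    cys_q = locate_anchor(sequence, v_res, v_seg)
    j_from = cys_q + 3 if cys_q is not None else v_res.q_end
    tail = sequence[j_from:]
    j_res = _best_by_score(aligner, tail, reference.segments(chain, "J"),
                           query_id, offset=j_from)
    if j_res is not None:
        out["J"] = j_res

    if chain == HEAVY and j_res is not None:
        # search for D between the anchors (the junction proper); local
        # alignments can clip a few boundary nucleotides, so the anchors are
        # the more reliable bounds
        j_seg = reference.get(chain, "J", j_res.gene)
        j_anchor_q = locate_anchor(sequence, j_res, j_seg)
        lo = cys_q + 3 if cys_q is not None else v_res.q_end
        hi = j_anchor_q if j_anchor_q is not None else j_res.q_start
        mid = sequence[lo:hi]
        cands = []
        for seg in reference.segments(chain, "D"):
            ln, a0, g0 = _longest_common_substring(mid, seg.seq)
            if ln >= MIN_D_CORE:
                q0 = lo + a0
                cands.append(AlignmentResult(
                    query_id=query_id, gene=seg.name, score=float(ln),
                    identity=100.0, q_start=q0, q_end=q0 + ln,
                    g_start=g0, g_end=g0 + ln, gaps=0,
                    blocks=(((q0, q0 + ln), (g0, g0 + ln)),),
                ))
        d_res = _best(cands)
        if d_res is not None:
            out["D"] = d_res
    return out


def check_productive(sequence: str, v_res: AlignmentResult, j_res: AlignmentResult | None,
                     v_seg: Segment, j_seg: Segment | None) -> tuple[bool, str, int | None, int | None]:
    """Productivity of a rearrangement given its V (and J) alignments.

    Returns (productive, reason, cys_end_q, j_anchor_q).  Productive means
    the junction is in-frame (anchor-to-anchor distance a multiple of 3) and
    the V-through-J translation in the V reading frame has no stop codon.
    """
    sequence = sequence.upper()
    cys_q = locate_anchor(sequence, v_res, v_seg)
    if cys_q is None:
        return False, "V 2nd-Cys anchor unmappable", None, None
    cys_end_q = cys_q + 3

    if j_res is None or j_seg is None:
        return False, "no J assignment", cys_end_q, None
    j_anchor_q = locate_anchor(sequence, j_res, j_seg)
    if j_anchor_q is None:
        return False, "J anchor unmappable", cys_end_q, None

    reasons = []
    if (j_anchor_q - cys_end_q) % 3 != 0:
        reasons.append("out-of-frame junction")
    # translate from the first full codon of the aligned V through the J match
    frame_anchor = cys_end_q  # codon boundary in the V reading frame
    start = (frame_anchor - v_res.q_start) % 3 + v_res.q_start
    region = sequence[start : j_res.q_end]
    region = region[: len(region) - len(region) % 3]
    if "*" in str(Seq(region).translate()):
        reasons.append("stop codon in V-J region")
    return (not reasons), "; ".join(reasons), cys_end_q, j_anchor_q


def extract_cdr3(sequence: str, cys_end_q: int | None, j_anchor_q: int | None
                 ) -> tuple[str | None, int | None]:
    """CDR3 amino acids strictly between the anchors (both excluded)."""
    if cys_end_q is None or j_anchor_q is None or j_anchor_q < cys_end_q:
        return None, None
    nt = sequence[cys_end_q:j_anchor_q]
    if len(nt) % 3 != 0:
        return None, None
    aa = str(Seq(nt).translate())
    return aa, len(aa)


def count_mutations(sequence: str, v_res: AlignmentResult, v_seg: Segment
                    ) -> tuple[list[tuple[int, str, str]], dict[str, int], int, int, int]:
    """List V-region mutations and tally them by region and by effect.

    Mutations are (germline position, germline base, query base) within the
    aligned V span, restricted to positions before the end of FR3.  Returns
    (mutations, region tallies, nt replacement, nt silent, aa replacements).
    """
    sequence = sequence.upper()
    fr3_end = v_seg.regions["fr3_end"]
    bounds = [(0, v_seg.regions["fr1_end"], "FR1"),
              (v_seg.regions["fr1_end"], v_seg.regions["cdr1_end"], "CDR1"),
              (v_seg.regions["cdr1_end"], v_seg.regions["fr2_end"], "FR2"),
              (v_seg.regions["fr2_end"], v_seg.regions["cdr2_end"], "CDR2"),
              (v_seg.regions["cdr2_end"], fr3_end, "FR3")]

    muts: list[tuple[int, str, str]] = []
    g2q: dict[int, int] = {}
    for (qs, qe), (gs, ge) in v_res.blocks:
        for i in range(ge - gs):
            g = gs + i
            if g >= fr3_end:
                break
            g2q[g] = qs + i
            if v_seg.seq[g] != sequence[qs + i]:
                muts.append((g, v_seg.seq[g], sequence[qs + i]))

    tallies = {r: 0 for r in REGIONS}
    for g, _, _ in muts:
        for lo, hi, name in bounds:
            if lo <= g < hi:
                tallies[name] += 1
                break

    replacement = silent = aa_repl = 0
    by_codon: dict[int, list[tuple[int, str, str]]] = {}
    for m in muts:
        by_codon.setdefault(m[0] // 3, []).append(m)
    for codon_idx, cm in by_codon.items():
        germ = v_seg.seq[codon_idx * 3 : codon_idx * 3 + 3]
        if len(germ) < 3:
            continue
        mutated = list(germ)
        for g, _, to in cm:
            mutated[g % 3] = to
        changed = str(Seq(germ).translate()) != str(Seq("".join(mutated)).translate())
        if changed:
            aa_repl += 1
            replacement += len(cm)
        else:
            silent += len(cm)
    return muts, tallies, replacement, silent, aa_repl


def annotate_sequence(
    sequence: str,
    reference: GermlineReference,
    chain: str,
    *,
    query_id: str = "query",
    aligner: PairwiseAligner | None = None,
) -> ChainAnnotation:
    """Annotate one chain: segments, productivity, CDR3, mutation counts."""
    ann = ChainAnnotation(id=query_id, chain=chain)
    try:
        res = assign_segments(sequence, reference, chain,
                              aligner=aligner, query_id=query_id)
    except AnnotationError as exc:
        ann.reason = str(exc)
        return ann
    sequence = sequence.upper()
    ann.alignments = res
    v_res = res["V"]
    j_res = res.get("J")
    v_seg = reference.get(chain, "V", v_res.gene)
    j_seg = reference.get(chain, "J", j_res.gene) if j_res else None
    ann.v_gene = v_res.gene
    ann.j_gene = j_res.gene if j_res else None
    ann.d_gene = res["D"].gene if "D" in res else None
    ann.v_identity = v_res.identity

    ann.productive, ann.reason, cys_end_q, j_anchor_q = check_productive(
        sequence, v_res, j_res, v_seg, j_seg)
    if cys_end_q is not None and j_anchor_q is not None:
        ann.junction_nt = sequence[cys_end_q - 3 : j_anchor_q + 3]
        ann.cdr3_aa, ann.cdr3_length = extract_cdr3(sequence, cys_end_q, j_anchor_q)

    (ann.mutations, ann.region_tallies, ann.nt_replacement,
     ann.nt_silent, ann.aa_replacements) = count_mutations(sequence, v_res, v_seg)
    return ann


def annotate_library(
    sequences: Mapping[tuple[str, str], str],
    reference: GermlineReference,
    *,
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Annotate a library of chains into a tidy per-hybridoma table.

    ``sequences`` maps (hybridoma id, chain) to nucleotide sequence; chains
    absent from the mapping appear as ``"NS"`` in the output, mirroring
    records whose chain could not be sequenced.  Output columns follow the
    published annotation-table shape (genes, CDR3, length per chain) plus
    mutation columns.  Annotation is order-independent: rows are sorted by id.
    """
    aligner = make_aligner()
    ids = sorted({rid for rid, _ in sequences})
    rows = []
    for rid in ids:
        row: dict = {"id": rid}
        for chain, tag in ((HEAVY, "heavy"), (KAPPA, "kappa")):
            seq = sequences.get((rid, chain))
            if seq is None:
                row.update({
                    f"{tag}_v": NS, f"{tag}_j": NS, f"{tag}_cdr3": NS,
                    f"{tag}_cdr3_length": pd.NA, f"{tag}_productive": False,
                    f"{tag}_reason": "no sequence", f"{tag}_mutations": "",
                    f"{tag}_nt_mutations": pd.NA, f"{tag}_nt_replacement": pd.NA,
                    f"{tag}_nt_silent": pd.NA, f"{tag}_aa_replacements": pd.NA,
                })
                if chain == HEAVY:
                    row["heavy_d"] = NS
                continue
            ann = annotate_sequence(seq, reference, chain, query_id=rid, aligner=aligner)
            from polyrep.simulate import serialize_mutations

            row.update({
                f"{tag}_v": ann.v_gene or NS,
                f"{tag}_j": ann.j_gene or NS,
                f"{tag}_cdr3": ann.cdr3_aa if ann.cdr3_aa is not None else NS,
                f"{tag}_cdr3_length": ann.cdr3_length,
                f"{tag}_productive": ann.productive,
                f"{tag}_reason": ann.reason,
                f"{tag}_mutations": serialize_mutations(ann.mutations),
                f"{tag}_nt_mutations": len(ann.mutations),
                f"{tag}_nt_replacement": ann.nt_replacement,
                f"{tag}_nt_silent": ann.nt_silent,
                f"{tag}_aa_replacements": ann.aa_replacements,
            })
            if chain == HEAVY:
                row["heavy_d"] = ann.d_gene or "-"
            for region, n in ann.region_tallies.items():
                row[f"{tag}_mut_{region}"] = n
        rows.append(row)
    out = pd.DataFrame(rows)
    if metadata is not None:
        out = metadata.merge(out, on="id", how="right")
    return out


def read_chain_fasta(*paths) -> dict[tuple[str, str], str]:
    """Read chain FASTA files with ids of the form ``<hybridoma>|<chain>``."""
    seqs: dict[tuple[str, str], str] = {}
    for path in paths:
        for rec in SeqIO.parse(str(path), "fasta"):
            rid, _, chain = rec.id.rpartition("|")
            if chain not in (HEAVY, KAPPA):
                raise AnnotationError(
                    f"FASTA id {rec.id!r}: expected '<id>|heavy' or '<id>|kappa'")
            seqs[(rid, chain)] = str(rec.seq)
    return seqs
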