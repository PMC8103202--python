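"""One-time generator for the bundled synthetic germline reference.

Produces FASTA files plus an anchors/region-boundary sidecar TSV under
src/polyrep/data/germline/. Sequences are synthetic: a single realistic
murine framework per locus, diversified deterministically per gene so that
genes are mutually distinguishable by alignment (pairwise distance far above
any simulated hypermutation load). Gene names follow IMGT-style mouse
nomenclature.
"""
from __future__ import annotations

import random
from pathlib import Path

OUT = Path(__file__).resolve().parents[1] / "src" / "polyrep" / "data" / "germline"

CODON = {
    "A": "GCC", "R": "AGA", "N": "AAC", "D": "GAC", "C": "TGT", "Q": "CAG",
    "E": "GAG", "G": "GGC", "H": "CAC", "I": "ATC", "L": "CTG", "K": "AAG",
    "M": "ATG", "F": "TTC", "P": "CCC", "S": "AGC", "T": "ACC", "W": "TGG",
    "Y": "TAC", "V": "GTG",
}

TABLE = {}


def _codon_table():
    from Bio.Data.CodonTable import standard_dna_table

    t = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        t[stop] = "*"
    return t


def rt(protein: str) -> str:
    return "".join(CODON[a] for a in protein)


def translate(nt: str) -> str:
    return "".join(TABLE[nt[i : i + 3]] for i in range(0, len(nt) - len(nt) % 3, 3))


HEAVY_FR1 = "EVQLQQSGAELVKPGASVKLSCKAS"   # 25
HEAVY_CDR1 = "GYTFTSYW"                   # 8
HEAVY_FR2 = "INWVKQRPGQGLEWIGE"           # 17
HEAVY_CDR2 = "ILPGSGST"                   # 8
HEAVY_FR3 = "NYNEKFKGKATLTADKSSSTAYMQLSSLTSEDSAVYYC"  # 38, ends with 2nd-Cys
HEAVY_TAIL = "AR"                         # germline-encoded CDR3 start

KAPPA_FR1 = "DIVMTQSPSSLAVSAGEKVTMSC"     # 23
KAPPA_CDR1 = "KSSQSLLNSG"                 # 10
KAPPA_FR2 = "WYQQKPGQSPKLLIY"             # 15
KAPPA_CDR2 = "WASTRES"                    # 7
KAPPA_FR3 = "GVPDRFTGSGSGTDFTLTISSVQAEDLAVYYC"  # 32, ends with 2nd-Cys

HEAVY_V_GENES = [
    "1-4", "1-7", "1-22", "1-26", "1-39", "1-43", "2-2", "2-5", "3-1",
    "3-3", "5-4", "5-6", "9-1", "10-3", "14-2",
]
KAPPA_V = {
    # gene -> germline-encoded CDR3 stub (7 residues after the 2nd-Cys)
    "3-4": "QQSKEFP",
    "3-10": "QQNNEDP",
    "4-74": "QQYHSDP",
    "4-91": "QHGSSLL",
    "5-45": "QQSNSWP",
    "6-20": "GQSYSYP",
    "10-94": "QQYSKLP",
    "12-44": "QHHYGTP",
    "12-46": "QHFYGTP",
    "13-85": "QQYWGTP",
}
HEAVY_D = {
    "1-1": "TCTACTATGGTTAC",
    "2-4": "AGGATAGTACCAGC",
    "3-3": "GCAAGGCTGGAACG",
    "4-1": "CCTCGACTAAGCAT",
    "2-12": "TTGTATCCCGGTTG",
}
HEAVY_J = {
    # nt before anchor | anchor TGG | FR4 remainder
    "1": ("TACTTTGACGTC", "TGGGGCGCAGGGACCACGGTCACCGTCTCCTCA"),   # ...YFDV W
    "2": ("TACTTTGACTAC", "TGGGGCCAAGGCACCACTCTCACAGTCTCCTCA"),   # ...YFDY W
    "3": ("TGGTTTGCTTAC", "TGGGGCCAAGGGACTCTGGTCACTGTCTCTGCA"),   # ...WFAY W
    "4": ("TACTATGCTATGGACTAC", "TGGGGTCAAGGAACCTCAGTCACCGTCTCCTCA"),  # ...YYAMDY W
}
KAPPA_J = {
    # nt before anchor | anchor TTC (F) | FR4 remainder
    "1": ("TGGACG", "TTCGGAGGGGGGACCAAGCTGGAAATAAAA"),   # WT F
    "2": ("TACACG", "TTCGGCGGAGGGACCAAGCTGGAGCTGAAA"),   # YT F
    "3": ("ATCACA", "TTCGGTGCTGGGACCAAGCTGGAGCTGAAA"),   # IT F
    "4": ("TTCACG", "TTCGGCTCGGGGACAAAGTTGGAAATAAAA"),   # FT F
    "5": ("CTCACG", "TTCGGTGGAGGCACCAAGCTGGAAATCAAA"),   # LT F
}


def diversify(base_nt: str, protected: range, seed: int, n_edits: int) -> str:
    """Deterministically mutate base_nt outside `protected`, avoiding stops."""
    rng = random.Random(seed)
    seq = list(base_nt)
    edits = 0
    while edits < n_edits:
        pos = rng.randrange(len(seq))
        if pos in protected:
            continue
        old = seq[pos]
        new = rng.choice([b for b in "ACGT" if b != old])
        saved = seq[pos]
        seq[pos] = new
        if "*" in translate("".join(seq)):
            seq[pos] = saved
            continue
        edits += 1
    return "".join(seq)


def main() -> None:
    global TABLE
    TABLE = _codon_table()
    OUT.mkdir(parents=True, exist_ok=True)

    heavy_base = rt(HEAVY_FR1 + HEAVY_CDR1 + HEAVY_FR2 + HEAVY_CDR2 + HEAVY_FR3 + HEAVY_TAIL)
    assert len(heavy_base) == 294
    cys_h = (len(HEAVY_FR1 + HEAVY_CDR1 + HEAVY_FR2 + HEAVY_CDR2 + HEAVY_FR3) - 1) * 3
    assert translate(heavy_base)[cys_h // 3] == "C"

    kappa_fr = KAPPA_FR1 + KAPPA_CDR1 + KAPPA_FR2 + KAPPA_CDR2 + KAPPA_FR3
    cys_k = (len(kappa_fr) - 1) * 3

    heavy_v = {}
    for i, name in enumerate(HEAVY_V_GENES):
        protected = range(cys_h, cys_h + 3)
        heavy_v[name] = diversify(heavy_base, protected, seed=1000 + i, n_edits=45)
        p = translate(heavy_v[name])
        assert p[cys_h // 3] == "C" and "*" not in p

    kappa_v = {}
    for i, (name, stub) in enumerate(sorted(KAPPA_V.items())):
        base = rt(kappa_fr) + rt(stub)
        protected = range(cys_k, len(base))  # keep Cys + CDR3 stub germline
        kappa_v[name] = diversify(base, protected, seed=2000 + i, n_edits=40)
        p = translate(kappa_v[name])
        assert p[cys_k // 3] == "C" and "*" not in p

    # pairwise distinguishability
    def hamming(a, b):
        return sum(x != y for x, y in zip(a, b))

    vs = list(heavy_v.values())
    for i in range(len(vs)):
        for j in range(i + 1, len(vs)):
            assert hamming(vs[i], vs[j]) >= 25, (i, j, hamming(vs[i], vs[j]))
    vs = list(kappa_v.values())
    for i in range(len(vs)):
        for j in range(i + 1, len(vs)):
            assert hamming(vs[i][:cys_k], vs[j][:cys_k]) >= 20

    # D genes: no shared substring of length >= 5 between any pair
    def kmers(s, k=5):
        return {s[i : i + k] for i in range(len(s) - k + 1)}

    names = list(HEAVY_D)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            shared = kmers(HEAVY_D[names[i]]) & kmers(HEAVY_D[names[j]])
            assert not shared, (names[i], names[j], shared)

    def wf(path, records):
        with open(path, "w") as fh:
            for name, seq in records:
                fh.write(f">{name}\n{seq}\n")

    wf(OUT / "heavy_v.synthetic.fasta", sorted(heavy_v.items()))
    wf(OUT / "heavy_d.synthetic.fasta", sorted(HEAVY_D.items()))
    wf(OUT / "heavy_j.synthetic.fasta", [(n, a + b) for n, (a, b) in sorted(HEAVY_J.items())])
    wf(OUT / "kappa_v.synthetic.fasta", sorted(kappa_v.items()))
    wf(OUT / "kappa_j.synthetic.fasta", [(n, a + b) for n, (a, b) in sorted(KAPPA_J.items())])

    rows = ["locus\trole\tgene\tanchor_start\tfr1_end\tcdr1_end\tfr2_end\tcdr2_end\tfr3_end"]
    b_h = (75, 99, 150, 174, 288)
    for name in sorted(heavy_v):
        rows.append("heavy\tV\t%s\t%d\t%s" % (name, cys_h, "\t".join(map(str, b_h))))
    b_k = (69, 99, 144, 165, 261)
    for name in sorted(kappa_v):
        rows.append("kappa\tV\t%s\t%d\t%s" % (name, cys_k, "\t".join(map(str, b_k))))
    for name in sorted(HEAVY_D):
        rows.append(f"heavy\tD\t{name}\t\t\t\t\t\t")
    for name, (pre, _) in sorted(HEAVY_J.items()):
        rows.append(f"heavy\tJ\t{name}\t{len(pre)}\t\t\t\t\t")
    for name, (pre, _) in sorted(KAPPA_J.items()):
        rows.append(f"kappa\tJ\t{name}\t{len(pre)}\t\t\t\t\t")
    (OUT / "anchors.tsv").write_text("\n".join(rows) + "\n")
    print("germline written to", OUT)


if __name__ == "__main__":
    main()
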