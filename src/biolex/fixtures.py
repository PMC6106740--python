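"""Seeded generators of small, well-formed example files in every format.

These stand in for downloaded examples: each call is fully determined by
(format, params, seed), valid per the format's own specification, and sized
by parameters rather than committed files.  No biological realism is
attempted (no reference genome, no alignment semantics) — only structural
validity, plus the features the lexers care about: IUPAC-ambiguous bases,
per-position quality decay, PCR-duplicate pairs in SAM, coding features in
GTF, fixed-column ATOM records in PDB, and a CLUSTAL conservation line.
"""

from __future__ import annotations

import random
from typing import Dict, List, Optional

from .core import FormatId

__all__ = ["generate_fixture", "FIXTURE_DEFAULTS"]

#: per-format parameter names and defaults
FIXTURE_DEFAULTS: Dict[FormatId, Dict[str, object]] = {
    FormatId.FASTA: {"n_records": 5, "seq_length": 120, "gc_fraction": 0.5,
                     "alphabet": "nucleotide"},
    FormatId.FASTQ: {"n_records": 10, "read_length": 60, "gc_fraction": 0.5},
    FormatId.SAM: {"n_records": 30, "read_length": 50, "gc_fraction": 0.5,
                   "dup_fraction": 0.0, "ambiguity_rate": 0.02},
    FormatId.VCF: {"n_records": 15, "n_samples": 2},
    FormatId.BED: {"n_records": 12},
    FormatId.GTF: {"n_records": 12},
    FormatId.PDB: {"n_records": 20},
    FormatId.CLUSTAL: {"n_records": 4, "seq_length": 60},
}

_AMBIG = "RYSWKMBDHVN"
_AA = "ACDEFGHIKLMNPQRSTVWY"


def _check_params(fmt: FormatId, params: Optional[dict]) -> dict:
    base = dict(FIXTURE_DEFAULTS[fmt])
    for key, value in (params or {}).items():
        if key not in base:
            raise ValueError(f"unknown parameter {key!r} for {fmt.value} fixture")
        base[key] = value
    for key in ("n_records", "read_length", "seq_length", "n_samples"):
        if key in base and (not isinstance(base[key], int) or base[key] < 0):
            raise ValueError(f"{key} must be a non-negative integer")
    for key in ("gc_fraction", "dup_fraction", "ambiguity_rate"):
        if key in base and not 0.0 <= float(base[key]) <= 1.0:
            raise ValueError(f"{key} must be in [0, 1]")
    if base.get("read_length") == 0 or base.get("seq_length") == 0:
        raise ValueError("sequence length must be >= 1")
    return base


def _seq(rng: random.Random, n: int, gc: float, ambiguity: float = 0.0) -> str:
    out = []
    for _ in range(n):
        if ambiguity and rng.random() < ambiguity:
            out.append(rng.choice(_AMBIG))
        elif rng.random() < gc:
            out.append(rng.choice("GC"))
        else:
            out.append(rng.choice("AT"))
    return "".join(out)


def _qual(rng: random.Random, n: int) -> str:
    """PHRED+33 string with linear per-position decay from ~38 to ~18."""
    chars = []
    for i in range(n):
        base = 38.0 - 20.0 * i / max(n - 1, 1)
        q = int(round(base + rng.gauss(0.0, 2.0)))
        q = max(2, min(40, q))
        chars.append(chr(q + 33))
    return "".join(chars)


def _fasta(p: dict, rng: random.Random) -> str:
    lines: List[str] = []
    aa = p["alphabet"] == "aminoacid"
    for i in range(p["n_records"]):
        lines.append(f">seq{i + 1} synthetic example record {i + 1}")
        if aa:
            seq = "".join(rng.choice(_AA) for _ in range(p["seq_length"]))
        else:
            seq = _seq(rng, p["seq_length"], p["gc_fraction"], 0.02)
        for j in range(0, len(seq), 60):
            lines.append(seq[j : j + 60])
    return "\n".join(lines) + ("\n" if lines else "")


def _fastq(p: dict, rng: random.Random) -> str:
    lines: List[str] = []
    for i in range(p["n_records"]):
        lines.append(f"@read{i + 1} synthetic")
        lines.append(_seq(rng, p["read_length"], p["gc_fraction"], 0.02))
        lines.append("+")
        lines.append(_qual(rng, p["read_length"]))
    return "\n".join(lines) + ("\n" if lines else "")


_CIGAR_SHAPES = (
    lambda L: f"{L}M",
    lambda L: f"{L - 6}M6S",
    lambda L: f"4S{L - 4}M",
    lambda L: f"{L // 2}M2I{L - L // 2 - 2}M",
    lambda L: f"{L // 2}M3D{L - L // 2}M",
)


def _sam(p: dict, rng: random.Random) -> str:
    n, L = p["n_records"], p["read_length"]
    lines = [
        "@HD\tVN:1.5\tSO:coordinate",
        "@SQ\tSN:chr1\tLN:248956422",
        "@RG\tID:rg1\tSM:sample1\tLB:lib1\tPL:ILLUMINA",
        "@PG\tID:gen\tPN:biolex-fixtures\tVN:0.1.0",
    ]
    records: List[tuple] = []
    for i in range(n):
        if records and rng.random() < p["dup_fraction"]:
            pos, seq = rng.choice(records)[:2]
            flag = 1024  # PCR-duplicate bit on an unpaired read
        else:
            pos = rng.randint(10_000, 1_000_000)
            seq = _seq(rng, L, p["gc_fraction"], p["ambiguity_rate"])
            flag = rng.choice((0, 16))
        records.append((pos, seq, flag, i))
    records.sort(key=lambda r: r[0])
    for pos, seq, flag, i in records:
        cigar = rng.choice(_CIGAR_SHAPES)(L) if L >= 12 else f"{L}M"
        mapq = rng.randint(0, 60)
        qual = _qual(rng, L)
        nm = rng.randint(0, 3)
        lines.append(
            f"read{i + 1}\t{flag}\tchr1\t{pos}\t{mapq}\t{cigar}\t=\t{pos}\t0\t"
            f"{seq}\t{qual}\tNM:i:{nm}\tRG:Z:rg1"
        )
    return "\n".join(lines) + "\n"


def _vcf(p: dict, rng: random.Random) -> str:
    samples = [f"S{i + 1}" for i in range(p["n_samples"])]
    lines = [
        "##fileformat=VCFv4.2",
        "##source=biolex-fixtures",
        "##contig=<ID=chr1,length=248956422>",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Sample depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    pos = 0
    for i in range(p["n_records"]):
        pos += rng.randint(100, 5000)
        ref = rng.choice("ACGT")
        alt = rng.choice([b for b in "ACGT" if b != ref])
        qual = round(rng.uniform(5, 99), 1)
        dp = rng.randint(5, 200)
        af = round(rng.random(), 3)
        gts = "\t".join(
            f"{rng.choice(('0/0', '0/1', '1/1'))}:{rng.randint(1, dp)}"
            for _ in samples
        )
        row = f"chr1\t{pos}\trs{rng.randint(10**5, 10**7)}\t{ref}\t{alt}\t{qual}\tPASS\tDP={dp};AF={af}\tGT:DP"
        if gts:
            row += "\t" + gts
        lines.append(row)
    return "\n".join(lines) + "\n"


def _bed(p: dict, rng: random.Random) -> str:
    lines: List[str] = []
    pos = 0
    for i in range(p["n_records"]):
        pos += rng.randint(500, 20_000)
        end = pos + rng.randint(100, 3000)
        score = rng.randint(0, 1000)
        strand = rng.choice("+-")
        lines.append(f"chr1\t{pos}\t{end}\tregion{i + 1}\t{score}\t{strand}")
    return "\n".join(lines) + ("\n" if lines else "")


_GTF_FEATURES = ("gene", "transcript", "exon", "CDS", "start_codon",
                 "stop_codon", "5UTR", "3UTR")


def _gtf(p: dict, rng: random.Random) -> str:
    lines: List[str] = []
    pos = 1000
    for i in range(p["n_records"]):
        feature = _GTF_FEATURES[i % len(_GTF_FEATURES)]
        pos += rng.randint(200, 8000)
        end = pos + rng.randint(50, 2000)
        score = rng.choice([".", str(rng.randint(0, 1000))])
        strand = rng.choice("+-")
        frame = rng.choice(("0", "1", "2")) if feature == "CDS" else "."
        gene = f"GENE{i // len(_GTF_FEATURES) + 1}"
        attrs = f'gene_id "{gene}"; transcript_id "{gene}.1"; exon_number {i % 9 + 1};'
        lines.append(
            f"chr1\tbiolex\t{feature}\t{pos}\t{end}\t{score}\t{strand}\t{frame}\t{attrs}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


_PDB_ATOMS = (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"))
_PDB_RES = ("ALA", "GLY", "SER", "LEU", "LYS", "TRP", "PHE", "GLU")


def _pdb(p: dict, rng: random.Random) -> str:
    lines = [
        "HEADER    SYNTHETIC STRUCTURE                     01-JAN-20   XXXX",
        "TITLE     GENERATED EXAMPLE COORDINATES",
    ]
    serial = 0
    res_seq = 0
    for i in range(p["n_records"]):
        if i % len(_PDB_ATOMS) == 0:
            res_seq += 1
            res = rng.choice(_PDB_RES)
        name, element = _PDB_ATOMS[i % len(_PDB_ATOMS)]
        serial += 1
        x, y, z = (round(rng.uniform(-40, 40), 3) for _ in range(3))
        occ = 1.00
        bfac = round(rng.uniform(5, 95), 2)
        # PDB v3.3 ATOM layout: name cols 13-16, altLoc 17, resName 18-20,
        # chain 22, resSeq 23-26, coords 31-54, occ 55-60, B 61-66, element 77-78
        lines.append(
            f"ATOM  {serial:5d}  {name:<3s} {res:>3s} A{res_seq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bfac:6.2f}          "
            f"{element:>2s}  "
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def _clustal(p: dict, rng: random.Random) -> str:
    n, L = p["n_records"], p["seq_length"]
    lines = ["CLUSTAL W (1.2.4) multiple sequence alignment", ""]
    base = [rng.choice(_AA) for _ in range(L)]
    seqs: List[str] = []
    for _ in range(n):
        row = [
            c if rng.random() < 0.7 else rng.choice(_AA + "-") for c in base
        ]
        seqs.append("".join(row))
    width = max(len(f"seq{i + 1}") for i in range(max(n, 1))) + 6
    for block in range(0, L, 60):
        for i, s in enumerate(seqs):
            name = f"seq{i + 1}"
            lines.append(f"{name:<{width}}{s[block:block + 60]}")
        cons = []
        for j in range(block, min(block + 60, L)):
            col = {s[j] for s in seqs}
            if len(col) == 1 and "-" not in col:
                cons.append("*")
            elif len(col) <= 2 and "-" not in col:
                cons.append(":")
            elif len(col) <= 3 and "-" not in col:
                cons.append(".")
            else:
                cons.append(" ")
        if n:
            lines.append(" " * width + "".join(cons))
        lines.append("")
    return "\n".join(lines) + "\n"


_GENERATORS = {
    FormatId.FASTA: _fasta,
    FormatId.FASTQ: _fastq,
    FormatId.SAM: _sam,
    FormatId.VCF: _vcf,
    FormatId.BED: _bed,
    FormatId.GTF: _gtf,
    FormatId.PDB: _pdb,
    FormatId.CLUSTAL: _clustal,
}


def generate_fixture(
    format: FormatId, params: Optional[dict] = None, seed: int = 0
) -> str:
    """Deterministic well-formed example text for one format.

    The output is fully determined by (format, params, seed); unknown or
    out-of-range parameters raise ValueError.
    """
    if format is FormatId.PLAIN:
        raise ValueError("cannot generate a PLAIN fixture")
    p = _check_params(format, params)
    rng = random.Random(seed)
    return _GENERATORS[format](p, rng)
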