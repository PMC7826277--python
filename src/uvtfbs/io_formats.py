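"""Readers and writers for the file formats the pipeline consumes.

Coordinate conventions
----------------------
Everything internal is 0-based, half-open (BED-native).  The only 1-based
surface is the mutations TSV, converted exactly once on read/write.

CPD (cyclobutane pyrimidine dimer) records are stored with ``pos5`` = the
*leftmost* genomic coordinate of the dipyrimidine, so the lesion occupies
``(pos5, pos5+1)``.  On the ``-`` strand the two reference bases are the
complement of a pyrimidine pair, i.e. they read as purines (A/G) on the
reference.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")
VALID_BASES = frozenset("ACGTN")

# base codes: A=0 C=1 G=2 T=3 N=4; complement(c) = 3-c for c<4
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


class FormatError(ValueError):
    """A file violates its declared format."""


def encode_seq(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0, C=1, G=2, T=3, N=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_seq(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse-complement an encoded sequence (N maps to N)."""
    out = np.where(codes < 4, 3 - codes, 4).astype(np.uint8)
    return out[::-1]


class GenomeSequence(Mapping):
    """Reference genome: mapping chromosome name -> uppercase ACGTN string.

    Sequences are stored encoded (uint8 codes) for vectorised work;
    ``genome[chrom]`` returns the plain string.
    """

    def __init__(self, sequences: Mapping[str, str] | Mapping[str, np.ndarray]):
        self._codes: dict[str, np.ndarray] = {}
        for name, seq in sequences.items():
            if isinstance(seq, np.ndarray):
                codes = seq.astype(np.uint8)
            else:
                seq = seq.upper()
                bad = set(seq) - VALID_BASES
                if bad:
                    raise FormatError(
                        f"chromosome {name!r} contains invalid characters {sorted(bad)}"
                    )
                codes = encode_seq(seq)
            if codes.size < 1:
                raise FormatError(f"chromosome {name!r} is empty")
            self._codes[name] = codes

    def __getitem__(self, chrom: str) -> str:
        return decode_seq(self._codes[chrom])

    def __iter__(self) -> Iterator[str]:
        return iter(self._codes)

    def __len__(self) -> int:
        return len(self._codes)

    def codes(self, chrom: str) -> np.ndarray:
        """Encoded sequence (read-only view)."""
        return self._codes[chrom]

    def length(self, chrom: str) -> int:
        return self._codes[chrom].size

    def base_composition(self) -> np.ndarray:
        """Genome-wide A,C,G,T frequencies (N excluded), summing to 1."""
        counts = np.zeros(5, dtype=np.int64)
        for codes in self._codes.values():
            counts += np.bincount(codes, minlength=5)
        acgt = counts[:4].astype(float)
        if acgt.sum() == 0:
            raise FormatError("genome contains no A/C/G/T bases")
        return acgt / acgt.sum()


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    score: float = 0.0

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


class MutationRecord(NamedTuple):
    sample: str
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str


class CPDRecord(NamedTuple):
    chrom: str
    pos5: int  # 0-based, leftmost base of the dipyrimidine
    strand: str
    count: int
    timepoint: str


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a FASTA file; uppercase; non-ACGTN characters become N (warned)."""
    from Bio import SeqIO

    path = Path(path)
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if not name:
            raise FormatError(f"{path}: empty FASTA header")
        if name in seqs:
            raise FormatError(f"{path}: duplicate header {name!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty sequence for {name!r}")
        n_bad = sum(1 for c in seq if c not in VALID_BASES)
        if n_bad:
            log.warning("%s: %d non-ACGTN characters in %s mapped to N", path, n_bad, name)
            seq = "".join(c if c in VALID_BASES else "N" for c in seq)
        seqs[name] = seq
    if not seqs:
        raise FormatError(f"{path}: no FASTA records")
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 (0-based half-open); column 6 is the strand if present."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
            chrom, start_s, end_s = cols[0], cols[1], cols[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise FormatError(
                    f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}"
                )
            name = cols[3] if len(cols) > 3 else "."
            try:
                score = float(cols[4]) if len(cols) > 4 and cols[4] != "." else 0.0
            except ValueError:
                score = 0.0
            strand = cols[5] if len(cols) > 5 else "."
            out.append(GenomicInterval(chrom, start, end, strand, name, score))
    return out


def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    """Write BED6 (byte round-trips with read_bed for 6-column input)."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = int(iv.score) if float(iv.score).is_integer() else iv.score
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# JASPAR PFM

def read_jaspar_pfm(path: str | Path):
    """Read one motif in JASPAR text format (4 rows A/C/G/T of equal length).

    Accepts both the bracketed JASPAR dialect::

        >MA0001.1 NAME
        A [ 10  2  0 ]
        ...

    and the bare 4-row matrix.  Returns a :class:`uvtfbs.tfbs_catalog.MotifModel`.
    """
    from .tfbs_catalog import MotifModel

    path = Path(path)
    motif_id, tf_name = path.stem, path.stem
    rows: list[list[float]] = []
    row_bases: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                parts = line[1:].split()
                if parts:
                    motif_id = parts[0]
                    tf_name = parts[1] if len(parts) > 1 else parts[0]
                continue
            base = None
            if line[0].upper() in "ACGT" and (len(line) == 1 or not line[1].isdigit() or line[1] in " \t["):
                base = line[0].upper()
                line = line[1:]
            line = line.replace("[", " ").replace("]", " ")
            try:
                values = [float(x) for x in line.split()]
            except ValueError as exc:
                raise FormatError(f"{path}: unparseable PFM row") from exc
            if not values:
                continue
            rows.append(values)
            row_bases.append(base or "ACGT"[len(rows) - 1])
    if len(rows) != 4:
        raise FormatError(f"{path}: expected 4 PFM rows (A,C,G,T), got {len(rows)}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise FormatError(f"{path}: PFM rows have unequal lengths {sorted(lengths)}")
    order = {b: i for i, b in enumerate(row_bases)}
    if set(order) != set("ACGT"):
        raise FormatError(f"{path}: PFM rows must cover A,C,G,T exactly once")
    counts = np.array([rows[order[b]] for b in "ACGT"], dtype=float)
    if np.any(counts < 0):
        raise FormatError(f"{path}: negative PFM count")
    if np.any(counts.sum(axis=0) <= 0):
        raise FormatError(f"{path}: all-zero PFM column (uninformative position)")
    return MotifModel(motif_id=motif_id, tf_name=tf_name, tf_family="", counts=counts)


def write_jaspar_pfm(motif, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{motif.motif_id} {motif.tf_name}\n")
        for i, base in enumerate("ACGT"):
            vals = " ".join(f"{v:g}" for v in motif.counts[i])
            fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# Mutations

MUTATION_COLUMNS = ["sample", "chrom", "pos", "ref", "alt"]


def _validate_ref(df: pd.DataFrame, genome: GenomeSequence, path) -> None:
    bad: list[str] = []
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in genome:
            bad.extend(f"{chrom}:{p + 1}" for p in sub["pos"].head(5))
            continue
        codes = genome.codes(chrom)
        pos = sub["pos"].to_numpy()
        refs = np.array([_CODE[ord(r)] for r in sub["ref"]])
        oob = (pos < 0) | (pos >= codes.size)
        mismatch = oob | (codes[np.clip(pos, 0, codes.size - 1)] != refs)
        if mismatch.any():
            for p, r in zip(pos[mismatch][:10], sub["ref"].to_numpy()[mismatch][:10]):
                bad.append(f"{chrom}:{p + 1} ref={r}")
    if bad:
        raise FormatError(
            f"{path}: {len(bad)}+ mutation records disagree with the genome: "
            + "; ".join(bad[:10])
        )


def read_mutations(path: str | Path, genome: GenomeSequence | None = None) -> pd.DataFrame:
    """Read somatic SNVs from a TSV (1-based) or VCF into a 0-based DataFrame.

    TSV columns: ``sample chrom pos ref alt`` (header required, 1-based
    positions).  VCF: SNV records only; indels and multi-base alleles are
    skipped with a warning.  Columns of the result: sample, chrom, pos
    (0-based), ref, alt.
    """
    path = Path(path)
    if path.suffix in (".vcf",) or path.name.endswith(".vcf.gz"):
        df = _read_mutations_vcf(path)
    else:
        df = _read_mutations_tsv(path)
    if genome is not None:
        _validate_ref(df, genome, path)
    return df


def _read_mutations_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample": str, "chrom": str})
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df = df[MUTATION_COLUMNS].copy()
    df["ref"] = df["ref"].str.upper()
    df["alt"] = df["alt"].str.upper()
    snv = df["ref"].isin(list("ACGT")) & df["alt"].isin(list("ACGT"))
    n_skipped = int((~snv).sum())
    if n_skipped:
        log.warning("%s: skipped %d non-SNV records", path, n_skipped)
        df = df[snv].copy()
    if (df["ref"] == df["alt"]).any():
        n = int((df["ref"] == df["alt"]).sum())
        raise FormatError(f"{path}: {n} records with ref == alt")
    df["pos"] = df["pos"].astype(np.int64) - 1  # 1-based at the boundary only
    if (df["pos"] < 0).any():
        raise FormatError(f"{path}: position < 1 in 1-based TSV")
    df.attrs["n_skipped"] = n_skipped
    return df.reset_index(drop=True)


def _read_mutations_vcf(path: Path) -> pd.DataFrame:
    import pysam

    rows = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples) or ["sample1"]
        default_sample = samples[0]
        for rec in vcf.fetch() if path.name.endswith(".gz") else vcf:
            ref = (rec.ref or "").upper()
            for alt in rec.alts or ():
                alt = (alt or "").upper()
                if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
                    n_skipped += 1
                    continue
                if ref == alt:
                    raise FormatError(f"{path}: ref == alt at {rec.chrom}:{rec.pos}")
                rows.append((default_sample, rec.chrom, rec.start, ref, alt))
    if n_skipped:
        log.warning("%s: skipped %d non-SNV VCF records", path, n_skipped)
    df = pd.DataFrame(rows, columns=MUTATION_COLUMNS)
    df.attrs["n_skipped"] = n_skipped
    return df


def write_mutations(df: pd.DataFrame, path: str | Path) -> None:
    """Write the mutations TSV (positions converted back to 1-based)."""
    out = df[MUTATION_COLUMNS].copy()
    out["pos"] = out["pos"].astype(np.int64) + 1
    with open(path, "w") as fh:
        fh.write("# uvtfbs mutations TSV; pos is 1-based\n")
        out.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CPD maps

CPD_COLUMNS = ["chrom", "pos5", "strand", "count"]


def read_cpd_map(
    path: str | Path, timepoint: str, genome: GenomeSequence | None = None
) -> pd.DataFrame:
    """Read a single-nucleotide CPD map (BED-like, 0-based).

    Columns: chrom, start (=pos5, leftmost base of the dipyrimidine),
    end (=pos5+1), count, strand.  When a genome is supplied, records whose
    two bases are not a dipyrimidine on the declared strand are dropped and
    counted in ``df.attrs["n_dropped"]``.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "pos5", "end", "count", "strand"],
        dtype={"chrom": str, "strand": str},
    )
    if df["count"].lt(0).any():
        raise FormatError(f"{path}: negative CPD count")
    if not df["strand"].isin(["+", "-"]).all():
        raise FormatError(f"{path}: CPD strand must be + or -")
    df = df[["chrom", "pos5", "strand", "count"]].copy()
    df["pos5"] = df["pos5"].astype(np.int64)
    df["count"] = df["count"].astype(np.int64)
    n_dropped = 0
    if genome is not None:
        keep_parts = []
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in genome:
                n_dropped += len(sub)
                continue
            codes = genome.codes(chrom)
            pos = sub["pos5"].to_numpy()
            ok = (pos >= 0) & (pos + 1 < codes.size)
            b1 = codes[np.clip(pos, 0, codes.size - 1)]
            b2 = codes[np.clip(pos + 1, 0, codes.size - 1)]
            plus = sub["strand"].to_numpy() == "+"
            # + strand: pyrimidine pair (C=1,T=3); - strand: purine pair (A=0,G=2)
            is_pyr = lambda b: (b == 1) | (b == 3)  # noqa: E731
            is_pur = lambda b: (b == 0) | (b == 2)  # noqa: E731
            ok &= np.where(plus, is_pyr(b1) & is_pyr(b2), is_pur(b1) & is_pur(b2))
            n_dropped += int((~ok).sum())
            keep_parts.append(sub[ok])
        df = pd.concat(keep_parts, ignore_index=True) if keep_parts else df.iloc[0:0]
        if n_dropped:
            log.warning("%s: dropped %d non-dipyrimidine CPD records", path, n_dropped)
    df.attrs["timepoint"] = timepoint
    df.attrs["n_dropped"] = n_dropped
    return df.reset_index(drop=True)


def write_cpd_map(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# uvtfbs CPD map; columns chrom,start,end,count,strand; 0-based\n")
        out = df.copy()
        out["end"] = out["pos5"] + 1
        out[["chrom", "pos5", "end", "count", "strand"]].to_csv(
            fh, sep="\t", index=False, header=False
        )
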