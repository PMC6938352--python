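"""Domain types and readers/writers for the external file formats.

Everything downstream consumes the containers defined here: an integer count
matrix keyed to the 2-pair x 2-allele NIL design, a genotype-class trait table,
TSS-anchored promoter sequences, an IUPAC motif library, a gene->term
annotation map, and the packaged 125-gene reference table.

Internal coordinates are 0-based half-open; GFF3 input (1-based inclusive) is
converted at the boundary.  Promoters are always reported 5'->3' into the gene
(minus-strand genes are reverse-complemented at extraction), with upstream
positions -1000..-1 and 5'UTR positions 0..L-1.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

ALLELES = ("F271", "F288")
#: genotype classes in canonical column order
GENOTYPE_CLASSES = ("1_F271", "1_F288", "2_F271", "2_F288")

#: IUPAC nucleotide degeneracy (motif-side; N in a *sequence* never matches)
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

TABLE1_SHA256 = "d05b189be88a3b26878446a205d1a40e69e70a0cae47f552b7038ce6c7363d93"


class FormatError(ValueError):
    """A delimited-text or sequence input violates the documented format."""


# ---------------------------------------------------------------------------
# sample design


@dataclass(frozen=True)
class SampleDesign:
    """One RNA-seq sample in the NIL layout."""

    sample_id: str
    nil_pair: int  # 1 or 2
    allele: str  # F271 or F288
    replicate: int

    def __post_init__(self):
        if self.nil_pair not in (1, 2):
            raise FormatError(f"{self.sample_id}: nil_pair must be 1 or 2, got {self.nil_pair}")
        if self.allele not in ALLELES:
            raise FormatError(f"{self.sample_id}: unknown allele {self.allele!r}")
        if self.replicate < 1:
            raise FormatError(f"{self.sample_id}: replicate must be >= 1")

    @property
    def genotype_class(self) -> str:
        return f"{self.nil_pair}_{self.allele}"


def validate_design(design: list[SampleDesign]) -> None:
    ids = [d.sample_id for d in design]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate sample ids in design")
    present = {d.genotype_class for d in design}
    missing = set(GENOTYPE_CLASSES) - present
    if missing:
        raise FormatError(f"empty genotype class(es): {sorted(missing)}")


def read_design(path: str | Path) -> list[SampleDesign]:
    """Read a tab-delimited design table (sample_id, nil_pair, allele, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "nil_pair", "allele", "replicate"}
    if not required <= set(df.columns):
        raise FormatError(f"design table must have columns {sorted(required)}")
    if df.isna().any().any():
        raise FormatError("design table contains missing values")
    design = [
        SampleDesign(r.sample_id, int(r.nil_pair), r.allele, int(r.replicate))
        for r in df.itertuples()
    ]
    validate_design(design)
    return design


def write_design(design: list[SampleDesign], path: str | Path) -> None:
    pd.DataFrame(
        [(d.sample_id, d.nil_pair, d.allele, d.replicate) for d in design],
        columns=["sample_id", "nil_pair", "allele", "replicate"],
    ).to_csv(path, sep="\t", index=False)


def study_design() -> list[SampleDesign]:
    """The unbalanced 2/1/2/2 layout of the original field experiment.

    Seven samples: two replicates per genotype class except 1_F288, where one
    of the two replicates was removed (stem-borer damage in the source study).
    """
    layout = [(1, "F271", 2), (1, "F288", 1), (2, "F271", 2), (2, "F288", 2)]
    design = []
    for pair, allele, nrep in layout:
        for rep in range(1, nrep + 1):
            design.append(SampleDesign(f"{pair}_{allele}_r{rep}", pair, allele, rep))
    return design


# ---------------------------------------------------------------------------
# count matrix


@dataclass
class CountMatrix:
    """Gene x sample non-negative integer counts."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_genes, n_samples) int64

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError("counts shape does not match gene/sample ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise FormatError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            g, s = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count at gene {self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids")

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def subset_genes(self, gene_ids: list[str]) -> "CountMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in gene_ids]
        return CountMatrix(list(gene_ids), list(self.sample_ids), self.counts[rows])

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return CountMatrix(list(self.gene_ids), list(sample_ids), self.counts[:, cols])


def read_counts(path: str | Path) -> CountMatrix:
    """Read a tab-delimited count table: first column gene id, then one integer
    column per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise FormatError(f"{path}: missing values in count table")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        bad = np.argwhere(arr != np.floor(arr))
        if len(bad):
            g, s = bad[0]
            raise FormatError(
                f"{path}: non-integer count at gene {df.index[g]!r}, column {df.columns[s]!r}"
            )
        arr = arr.astype(np.int64)
    if (arr < 0).any():
        g, s = np.argwhere(arr < 0)[0]
        raise FormatError(
            f"{path}: negative count at gene {df.index[g]!r}, column {df.columns[s]!r}"
        )
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    return CountMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), arr)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    pd.DataFrame(cm.counts, index=cm.gene_ids, columns=cm.sample_ids).to_csv(
        path, sep="\t", index_label="gene_id"
    )


def align_counts_to_design(cm: CountMatrix, design: list[SampleDesign]) -> CountMatrix:
    """Reorder count columns to design order, erroring on any mismatch."""
    want = [d.sample_id for d in design]
    if set(want) != set(cm.sample_ids):
        raise FormatError("count matrix samples do not match design samples")
    return cm.subset_samples(want)


# ---------------------------------------------------------------------------
# traits


@dataclass
class TraitTable:
    """One value per (genotype class, trait); classes in canonical order."""

    traits: list[str]
    values: np.ndarray  # (4 classes, n_traits)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(GENOTYPE_CLASSES), len(self.traits)):
            raise FormatError("trait table must be 4 classes x n_traits")
        if len(set(self.traits)) != len(self.traits):
            raise FormatError("duplicate trait names")

    def trait_vector(self, name: str) -> np.ndarray:
        return self.values[:, self.traits.index(name)]


def read_traits(path: str | Path) -> TraitTable:
    """Read a tab-delimited trait table: genotype_class column + one numeric
    column per trait."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric trait value ({exc})") from exc
    if df.isna().any().any():
        raise FormatError(f"{path}: missing trait values")
    if set(df.index) != set(GENOTYPE_CLASSES):
        raise FormatError(
            f"{path}: genotype classes must be exactly {GENOTYPE_CLASSES}, got {list(df.index)}"
        )
    df = df.loc[list(GENOTYPE_CLASSES)]
    return TraitTable(list(df.columns.astype(str)), df.to_numpy())


def write_traits(tt: TraitTable, path: str | Path) -> None:
    pd.DataFrame(tt.values, index=list(GENOTYPE_CLASSES), columns=tt.traits).to_csv(
        path, sep="\t", index_label="genotype_class"
    )


# ---------------------------------------------------------------------------
# promoters


@dataclass
class Promoter:
    """1,000 bp upstream + 5'UTR on the coding strand.

    ``sequence[i]`` sits at TSS-relative position ``start + i`` where
    ``start = -(len(sequence) - utr_length)``; start is -1000 unless the
    promoter was truncated at a contig edge.
    """

    gene_id: str
    sequence: str
    utr_length: int
    truncated: bool = False

    def __post_init__(self):
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise FormatError(f"{self.gene_id}: non-nucleotide characters {sorted(bad)}")
        self.sequence = self.sequence.upper()

    @property
    def start(self) -> int:
        return self.utr_length - len(self.sequence)

    @property
    def end(self) -> int:
        return self.utr_length


@dataclass
class PromoterSet:
    promoters: list[Promoter]
    n_excluded_short_utr: int = 0

    def __iter__(self):
        return iter(self.promoters)

    def __len__(self):
        return len(self.promoters)

    @property
    def max_utr(self) -> int:
        return max((p.utr_length for p in self.promoters), default=0)


UPSTREAM_LEN = 1000
MIN_UTR = 10

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _parse_gff3(path: str | Path) -> list[dict]:
    """Minimal GFF3 gene/five_prime_UTR parse; returns per-gene records with
    0-based half-open coordinates."""
    genes: dict[str, dict] = {}
    utrs: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise FormatError(f"{path}: malformed GFF3 line: {line[:60]}")
            seqid, _, ftype, start, end, _, strand, _, attrs = f
            start0, end0 = int(start) - 1, int(end)  # 1-based inclusive -> half-open
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                gid = attr.get("ID") or attr.get("Name")
                if gid is None:
                    raise FormatError(f"{path}: gene feature without ID")
                genes[gid] = dict(gene_id=gid, contig=seqid, start=start0, end=end0, strand=strand)
            elif ftype == "five_prime_UTR":
                gid = attr.get("Parent") or attr.get("ID")
                utrs.setdefault(gid, []).append((start0, end0))
    out = []
    for gid, g in genes.items():
        spans = utrs.get(gid, [])
        g["utr_length"] = sum(e - s for s, e in spans)
        out.append(g)
    return out


def read_promoters(fasta: str | Path, gff: str | Path) -> PromoterSet:
    """Extract 1,000 bp upstream + 5'UTR per gene from genome FASTA + GFF3.

    Genes with a 5'UTR shorter than 10 bases are excluded (counted).
    Minus-strand promoters are reverse-complemented so the axis always reads
    5'->3' into the gene.  Promoters running past a contig edge are truncated
    and flagged.
    """
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
    promoters, n_excluded = [], 0
    for g in _parse_gff3(gff):
        if g["contig"] not in contigs:
            raise FormatError(f"GFF contig {g['contig']!r} missing from FASTA")
        seq = contigs[g["contig"]]
        L = g["utr_length"]
        if L < MIN_UTR:
            n_excluded += 1
            continue
        if g["strand"] == "+":
            tss = g["start"]
            lo, hi = tss - UPSTREAM_LEN, tss + L
            truncated = lo < 0
            sub = seq[max(lo, 0): min(hi, len(seq))]
        elif g["strand"] == "-":
            tss = g["end"]  # half-open end == 0-based TSS position + 1
            lo, hi = tss - L, tss + UPSTREAM_LEN
            truncated = hi > len(seq)
            sub = revcomp(seq[max(lo, 0): min(hi, len(seq))])
        else:
            raise FormatError(f"{g['gene_id']}: strand must be + or -")
        promoters.append(Promoter(g["gene_id"], sub, L, truncated=truncated))
    if n_excluded:
        logger.info("read_promoters: excluded %d promoters with 5'UTR < %d bases",
                    n_excluded, MIN_UTR)
    return PromoterSet(promoters, n_excluded)


def read_promoter_table(path: str | Path) -> PromoterSet:
    """Pre-extracted promoter TSV: gene_id, utr_length, sequence."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "sequence": str})
    n_excl = 0
    proms = []
    for r in df.itertuples():
        if int(r.utr_length) < MIN_UTR:
            n_excl += 1
            continue
        proms.append(Promoter(r.gene_id, r.sequence, int(r.utr_length)))
    return PromoterSet(proms, n_excl)


def write_promoter_files(pset: PromoterSet, fasta_path: str | Path, gff_path: str | Path,
                         pad: int = 50) -> None:
    """Write a PromoterSet as contig-per-gene FASTA + GFF3 (round-trippable).

    Each promoter is embedded in its own synthetic plus-strand contig with
    ``pad`` A's on each side; the gene body is a 1 bp stub after the UTR.
    """
    fasta_recs, gff_lines = [], ["##gff-version 3"]
    for p in pset:
        if p.truncated:
            raise FormatError(f"{p.gene_id}: cannot serialize truncated promoter")
        contig = f"ctg_{p.gene_id}"
        seq = "A" * pad + p.sequence + "A" * pad
        tss0 = pad + UPSTREAM_LEN  # 0-based TSS position in contig
        gene_start1 = tss0 + 1
        gene_end1 = tss0 + p.utr_length + 1  # UTR + 1 bp stub
        fasta_recs.append((contig, seq))
        gff_lines.append(
            f"{contig}\tnilnet\tgene\t{gene_start1}\t{gene_end1}\t.\t+\t."
            f"\tID={p.gene_id}"
        )
        gff_lines.append(
            f"{contig}\tnilnet\tfive_prime_UTR\t{gene_start1}\t{tss0 + p.utr_length}\t.\t+\t."
            f"\tParent={p.gene_id}"
        )
    with open(fasta_path, "w") as fh:
        for name, seq in fasta_recs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i: i + 80] + "\n")
    Path(gff_path).write_text("\n".join(gff_lines) + "\n")


# ---------------------------------------------------------------------------
# motifs / annotations


@dataclass(frozen=True)
class Motif:
    name: str
    pattern: str

    def __post_init__(self):
        if not self.pattern:
            raise FormatError(f"motif {self.name!r}: empty pattern")
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise FormatError(f"motif {self.name!r}: non-IUPAC characters {sorted(bad)}")
        object.__setattr__(self, "pattern", self.pattern.upper())


@dataclass
class MotifLibrary:
    motifs: list[Motif]

    def __post_init__(self):
        names = [m.name for m in self.motifs]
        if len(set(names)) != len(names):
            raise FormatError("duplicate motif names")

    def __iter__(self):
        return iter(self.motifs)

    def __len__(self):
        return len(self.motifs)


def read_motifs(path: str | Path) -> MotifLibrary:
    """Motif TSV: name, IUPAC pattern."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"name", "pattern"} <= set(df.columns):
        raise FormatError(f"{path}: motif table needs columns name, pattern")
    return MotifLibrary([Motif(r.name, r.pattern) for r in df.itertuples()])


def write_motifs(lib: MotifLibrary, path: str | Path) -> None:
    pd.DataFrame([(m.name, m.pattern) for m in lib], columns=["name", "pattern"]).to_csv(
        path, sep="\t", index=False
    )


@dataclass
class GeneSetAnnotation:
    """gene_id -> set of term ids; the universe is every annotated gene."""

    gene_terms: dict[str, set[str]]

    @property
    def universe(self) -> set[str]:
        return set(self.gene_terms)

    def genes_with_term(self, term: str) -> set[str]:
        return {g for g, ts in self.gene_terms.items() if term in ts}

    @property
    def terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.gene_terms.values():
            out |= ts
        return out


def read_annotations(path: str | Path) -> GeneSetAnnotation:
    """Two-column TSV (gene, term); a GAF-like file with >=5 columns is also
    accepted (columns 2 and 5: gene, term)."""
    gene_terms: dict[str, set[str]] = {}
    with open(path) as fh:
        header_skipped = False
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("!") or line.startswith("#"):
                continue
            f = line.split("\t")
            if not header_skipped and f[0].lower() in ("gene", "gene_id"):
                header_skipped = True
                continue
            if len(f) >= 5:
                gene, term = f[1], f[4]
            elif len(f) == 2:
                gene, term = f
            else:
                raise FormatError(f"{path}: expected 2 or >=5 columns, got {len(f)}")
            if not term:
                raise FormatError(f"{path}: empty term for gene {gene!r}")
            gene_terms.setdefault(gene, set()).add(term)
    return GeneSetAnnotation(gene_terms)


def write_annotations(ann: GeneSetAnnotation, path: str | Path) -> None:
    rows = [(g, t) for g in sorted(ann.gene_terms) for t in sorted(ann.gene_terms[g])]
    pd.DataFrame(rows, columns=["gene", "term"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# packaged reference table


@dataclass(frozen=True)
class Table1Record:
    gene_id: str
    gene_name: str
    trend: str  # Up / Down
    pcc_ivndfd: float
    pcc_hcell: float
    pcc_cell: float
    pcc_lignin: float
    module: str  # M1..M7 or NA
    spe: str  # SPE_F271 / SPE_F288 / none
    in_qtl_region: bool
    in_qtl_locus: bool


def load_table1_fixture() -> list[Table1Record]:
    """Load the packaged 125-gene reference table (checksum-verified)."""
    data = resources.files("nilnet").joinpath("data/table1.tsv").read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != TABLE1_SHA256:
        raise FormatError(f"table1.tsv checksum mismatch: {digest}")
    df = pd.read_csv(
        resources.files("nilnet").joinpath("data/table1.tsv"), sep="\t",
        keep_default_na=False,
    )
    records = []
    for r in df.itertuples():
        records.append(Table1Record(
            gene_id=r.gene_id, gene_name=r.gene_name, trend=r.trend,
            pcc_ivndfd=float(r.pcc_ivndfd), pcc_hcell=float(r.pcc_hcell),
            pcc_cell=float(r.pcc_cell), pcc_lignin=float(r.pcc_lignin),
            module=r.module, spe=r.spe,
            in_qtl_region=str(r.in_qtl_region).lower() == "true",
            in_qtl_locus=str(r.in_qtl_locus).lower() == "true",
        ))
    if len(records) != 125:
        raise FormatError(f"table1 fixture must have 125 records, got {len(records)}")
    return records


def table1_dataframe() -> pd.DataFrame:
    """The reference table as a DataFrame (module 'NA' kept as a string)."""
    return pd.DataFrame([r.__dict__ for r in load_table1_fixture()])
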