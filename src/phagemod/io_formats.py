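"""Reading and writing of every external representation the pipeline touches.

Coordinate conventions
----------------------
All in-memory coordinates are 0-based half-open intervals on the plus strand.
Conversion to 1-based inclusive coordinates happens only at the GFF3 boundary;
BED shares the internal convention. Circular genomes are stored linearized at
a declared origin, with ``topology == "circular"`` recording the fact.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

from ._seq import encode

FEATURE_KINDS = {"tRNA", "gene", "repeat_unit", "repeat_region", "module", "other"}

#: Standard three-letter amino-acid codes accepted as tRNA labels.
AMINO_ACIDS = {
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
}


@dataclass
class Feature:
    """An annotated interval on a genome (0-based half-open)."""

    label: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "other"

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Genome:
    """A named nucleotide sequence with topology flag and feature annotations."""

    id: str
    sequence: str
    topology: str = "linear"
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be linear or circular, got {self.topology!r}")
        encode(self.sequence)  # validates the alphabet, lists offenders
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(
                    f"feature {f.label!r} interval [{f.start},{f.end}) exceeds genome length {len(self.sequence)}"
                )
            if f.kind == "tRNA" and f.label not in AMINO_ACIDS:
                raise ValueError(f"tRNA feature label {f.label!r} is not a standard amino acid")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PrimerEntry:
    name: str
    sequence: str
    role: str  # forward | reverse

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if self.role not in ("forward", "reverse"):
            raise ValueError(f"primer role must be forward/reverse, got {self.role!r}")
        if not (15 <= len(self.sequence) <= 40):
            raise ValueError(f"primer {self.name!r} length {len(self.sequence)} outside [15, 40]")
        encode(self.sequence, allow_n=False)


@dataclass
class PrimerPanel:
    entries: list[PrimerEntry] = field(default_factory=list)

    @property
    def forward(self) -> list[PrimerEntry]:
        return [e for e in self.entries if e.role == "forward"]

    @property
    def reverse(self) -> list[PrimerEntry]:
        return [e for e in self.entries if e.role == "reverse"]

    def get(self, name: str) -> PrimerEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)


@dataclass
class HostRangeMatrix:
    """Binary strain x phage lysis table from spot assays."""

    strains: list[tuple[str, str]]  # (strain id, species label)
    phages: list[str]
    lysis: "pd.DataFrame | None" = None  # set in __post_init__ from `values`
    values: "list[list[int]] | None" = None

    def __post_init__(self):
        import numpy as np

        if self.lysis is None:
            arr = np.asarray(self.values, dtype=np.int64)
        else:
            arr = np.asarray(self.lysis, dtype=np.int64)
        if arr.shape != (len(self.strains), len(self.phages)):
            raise ValueError(
                f"lysis matrix shape {arr.shape} does not match {len(self.strains)} strains x {len(self.phages)} phages"
            )
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("lysis entries must be 0 or 1")
        self.lysis = arr
        self.values = None

    def phage_column(self, phage: str):
        return self.lysis[:, self.phages.index(phage)]

    def species_of(self, strain_id: str) -> str:
        for sid, sp in self.strains:
            if sid == strain_id:
                return sp
        raise KeyError(strain_id)


# ---------------------------------------------------------------------------
# Genome I/O


def _genome_from_seqrecord(rec, fmt: str) -> Genome:
    seq = str(rec.seq).upper()
    feats: list[Feature] = []
    topology = "linear"
    if fmt == "genbank":
        topology = "circular" if rec.annotations.get("topology") == "circular" else "linear"
        for f in rec.features:
            if f.type not in ("tRNA", "gene", "CDS"):
                continue
            start, end = int(f.location.start), int(f.location.end)
            strand = "-" if f.location.strand == -1 else "+"
            if f.type == "tRNA":
                product = f.qualifiers.get("product", [""])[0]
                label = product.replace("tRNA-", "").strip() or "other"
                kind = "tRNA"
            else:
                label = (
                    f.qualifiers.get("gene", f.qualifiers.get("locus_tag", f.qualifiers.get("product", ["gene"])))
                )[0]
                kind = "gene"
            feats.append(Feature(label=label, start=start, end=end, strand=strand, kind=kind))
    return Genome(id=rec.id, sequence=seq, topology=topology, features=feats)


def read_genomes(path, format: str = "fasta") -> list[Genome]:
    """Read all records of a FASTA or GenBank flat file as Genome objects."""
    if format not in ("fasta", "genbank"):
        raise ValueError(f"unsupported genome format {format!r}")
    try:
        with open(path) as handle:
            records = list(SeqIO.parse(handle, format))
    except OSError:
        raise
    except Exception as exc:  # Biopython raises assorted exception types
        raise ValueError(f"malformed {format} file {path}: {exc}") from exc
    if not records:
        raise ValueError(f"no records parsed from {path} (malformed or empty {format})")
    return [_genome_from_seqrecord(r, format) for r in records]


def read_genome(path, format: str = "fasta") -> Genome:
    """Read a single-record FASTA/GenBank file (error if several records)."""
    genomes = read_genomes(path, format)
    if len(genomes) != 1:
        raise ValueError(f"{path} holds {len(genomes)} records; use read_genomes()")
    return genomes[0]


def write_fasta(genomes, path, width: int = 70) -> None:
    if isinstance(genomes, Genome):
        genomes = [genomes]
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i : i + width] + "\n")


def write_intervals(genome: Genome, kinds, path, format: str = "bed") -> None:
    """Write selected genome features as BED (0-based half-open) or GFF3
    (1-based inclusive)."""
    kinds = set(kinds)
    feats = [f for f in genome.features if f.kind in kinds]
    with open(path, "w") as fh:
        if format == "bed":
            fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
            for f in feats:
                fh.write(f"{genome.id}\t{f.start}\t{f.end}\t{f.label}\t0\t{f.strand}\n")
        elif format == "gff3":
            fh.write("##gff-version 3\n")
            for f in feats:
                attrs = f"ID={f.label};kind={f.kind}"
                fh.write(
                    f"{genome.id}\tphagemod\t{f.kind}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
                )
        else:
            raise ValueError(f"unsupported interval format {format!r}")


def read_intervals(path, format: str = "bed") -> list[Feature]:
    """Read a BED or GFF3 file written by :func:`write_intervals`."""
    feats: list[Feature] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if format == "bed":
                feats.append(Feature(label=cols[3], start=int(cols[1]), end=int(cols[2]), strand=cols[5]))
            elif format == "gff3":
                kind = cols[2] if cols[2] in FEATURE_KINDS else "other"
                label = "feature"
                for kv in cols[8].split(";"):
                    if kv.startswith("ID="):
                        label = kv[3:]
                feats.append(
                    Feature(label=label, start=int(cols[3]) - 1, end=int(cols[4]), strand=cols[6], kind=kind)
                )
            else:
                raise ValueError(f"unsupported interval format {format!r}")
    return feats


# ---------------------------------------------------------------------------
# Host-range matrix I/O


def read_hostrange(path) -> HostRangeMatrix:
    """Read a strain x phage spot-assay CSV.

    Layout: header row with phage ids; first two columns are strain id and
    species label; remaining cells are 0/1 lysis calls. Any other cell value
    (including empty) is an error naming its row and column — no imputation.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise ValueError("host-range CSV needs strain, species and at least one phage column")
    phages = list(df.columns[2:])
    strains = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
    values = []
    for i, row in df.iterrows():
        vals = []
        for p in phages:
            cell = row[p].strip()
            if cell not in ("0", "1"):
                raise ValueError(f"non-binary cell {cell!r} at strain {row.iloc[0]!r}, phage {p!r}")
            vals.append(int(cell))
        values.append(vals)
    return HostRangeMatrix(strains=strains, phages=phages, values=values)


def write_hostrange(matrix: HostRangeMatrix, path) -> None:
    df = pd.DataFrame(matrix.lysis, columns=matrix.phages)
    df.insert(0, "species", [sp for _, sp in matrix.strains])
    df.insert(0, "strain", [sid for sid, _ in matrix.strains])
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Primer panel I/O (TSV: name, sequence, role)


def read_primer_panel(path) -> PrimerPanel:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name", "sequence", "role"}
    if not required.issubset(df.columns):
        raise ValueError(f"primer TSV must have columns {sorted(required)}")
    entries = [PrimerEntry(r["name"], r["sequence"], r["role"]) for _, r in df.iterrows()]
    return PrimerPanel(entries=entries)


def write_primer_panel(panel: PrimerPanel, path) -> None:
    df = pd.DataFrame(
        [(e.name, e.sequence, e.role) for e in panel.entries],
        columns=["name", "sequence", "role"],
    )
    df.to_csv(path, sep="\t", index=False)
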