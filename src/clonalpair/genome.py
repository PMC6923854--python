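"""Annotated-genome container and plain-text genome I/O.

Internal coordinates are 0-based half-open throughout the package; the GFF3
reader/writer converts to/from the format's 1-based inclusive convention.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    """A typed genome feature in 0-based half-open coordinates."""

    replicon: str
    start: int
    end: int
    strand: str  # '+' or '-'
    ftype: str  # 'CDS', 'rRNA', 'tRNA', ...
    feature_id: str
    attributes: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad feature interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def shifted(self, delta_start: int, delta_end: int | None = None) -> "Feature":
        de = delta_start if delta_end is None else delta_end
        return replace(self, start=self.start + delta_start, end=self.end + de)


@dataclass
class AnnotatedGenome:
    """Replicon sequences plus typed features (CDS, rRNA, tRNA, ...)."""

    sequences: dict[str, str]
    features: list[Feature] = field(default_factory=list)
    topology: dict[str, str] = field(default_factory=dict)  # name -> linear|circular

    def __post_init__(self):
        for name in self.sequences:
            self.topology.setdefault(name, "linear")
        self.validate()

    # -- queries ----------------------------------------------------------
    @property
    def length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def replicon_names(self) -> list[str]:
        return list(self.sequences)

    def features_of(self, ftype: str, replicon: str | None = None) -> list[Feature]:
        return [
            f
            for f in self.features
            if f.ftype == ftype and (replicon is None or f.replicon == replicon)
        ]

    def cds(self, replicon: str | None = None) -> list[Feature]:
        return self.features_of("CDS", replicon)

    def gc_fraction(self, replicon: str | None = None) -> float:
        seqs = (
            [self.sequences[replicon]] if replicon else list(self.sequences.values())
        )
        gc = sum(s.count("G") + s.count("C") for s in seqs)
        n = sum(len(s) for s in seqs)
        return gc / n if n else 0.0

    def cds_sequence(self, feat: Feature) -> str:
        """CDS nucleotide sequence in coding orientation."""
        s = self.sequences[feat.replicon][feat.start : feat.end]
        return revcomp(s) if feat.strand == "-" else s

    def validate(self) -> None:
        for f in self.features:
            if f.replicon not in self.sequences:
                raise ValueError(f"feature {f.feature_id} on unknown replicon {f.replicon}")
            if f.end > len(self.sequences[f.replicon]):
                raise ValueError(f"feature {f.feature_id} exceeds replicon bounds")

    # -- I/O --------------------------------------------------------------
    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(s), id=name, description="") for name, s in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    def write_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name, s in self.sequences.items():
                fh.write(f"##sequence-region {name} 1 {len(s)}\n")
            for f in sorted(self.features, key=lambda f: (f.replicon, f.start)):
                attrs = ";".join(
                    [f"ID={f.feature_id}"]
                    + [f"{k}={v}" for k, v in f.attributes.items() if k != "ID"]
                )
                fh.write(
                    "\t".join(
                        [
                            f.replicon,
                            "clonalpair",
                            f.ftype,
                            str(f.start + 1),
                            str(f.end),
                            ".",
                            f.strand,
                            "0" if f.ftype == "CDS" else ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )

    @classmethod
    def from_files(cls, fasta: str | Path, gff3: str | Path | None = None) -> "AnnotatedGenome":
        sequences = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")
        }
        features: list[Feature] = []
        if gff3 is not None:
            features = read_gff3_features(gff3)
        return cls(sequences=sequences, features=features)


def read_gff3_features(gff3: str | Path, ftypes: tuple[str, ...] | None = None) -> list[Feature]:
    """Read features from a GFF3 file into 0-based half-open coordinates."""
    db = gffutils.create_db(
        str(gff3),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    out: list[Feature] = []
    for i, f in enumerate(db.all_features()):
        if ftypes is not None and f.featuretype not in ftypes:
            continue
        fid = f.attributes.get("ID", [f"feat{i}"])[0]
        attrs = {k: v[0] for k, v in f.attributes.items() if k != "ID"}
        out.append(
            Feature(
                replicon=f.seqid,
                start=f.start - 1,
                end=f.end,
                strand=f.strand if f.strand in "+-" else "+",
                ftype=f.featuretype,
                feature_id=fid,
                attributes=attrs,
            )
        )
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=n, description="") for n, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
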