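"""Reference genome, feature annotations and cytosine context classification.

In plant methylomes every cytosine is assigned to one of three sequence
contexts by the two bases downstream of it in the strand's own 5'->3'
direction: CG (next base G), CHG (next base H = A/C/T, then G) and CHH
(both downstream bases H).  Context is classified on both strands: a G on
the forward strand is a cytosine on the reverse strand, whose downstream
bases are the reverse complement of the two preceding forward-strand bases.

Coordinates are 0-based half-open throughout; GFF3 input (1-based
inclusive) is converted on read.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import NotACytosineError, OutOfBoundsError, ParseError

CONTEXTS = ("CG", "CHG", "CHH")

_A, _C, _G, _T, _N = (ord(b) for b in "ACGTN")

# Complement lookup over raw byte codes; anything that is not ACGT maps to N.
_COMPLEMENT = np.full(256, _N, dtype=np.uint8)
for _x, _y in ((_A, _T), (_T, _A), (_C, _G), (_G, _C)):
    _COMPLEMENT[_x] = _y

_IS_ACGT = np.zeros(256, dtype=bool)
_IS_ACGT[[_A, _C, _G, _T]] = True


class FeatureClass(str, enum.Enum):
    """The four annotated sequence classes profiled by the pipeline."""

    PROTEIN_CODING_GENE = "protein_coding_gene"
    PSEUDOGENE = "pseudogene"
    TRANSPOSABLE_ELEMENT = "transposable_element"
    REPEAT = "repeat"


#: Default mapping from GFF3 ``type`` values onto the four feature classes.
DEFAULT_CLASS_MAP: dict[str, FeatureClass] = {
    "gene": FeatureClass.PROTEIN_CODING_GENE,
    "protein_coding_gene": FeatureClass.PROTEIN_CODING_GENE,
    "mRNA": FeatureClass.PROTEIN_CODING_GENE,
    "pseudogene": FeatureClass.PSEUDOGENE,
    "transposable_element": FeatureClass.TRANSPOSABLE_ELEMENT,
    "transposable_element_gene": FeatureClass.TRANSPOSABLE_ELEMENT,
    "repeat_region": FeatureClass.REPEAT,
    "repeat": FeatureClass.REPEAT,
}


@dataclass(frozen=True)
class Feature:
    """An annotated interval: 0-based half-open ``[start, end)`` on ``contig``."""

    id: str
    feature_class: FeatureClass
    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not self.id:
            raise ValueError("feature id must be nonempty")
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"feature {self.id}: require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Genomic position of the strand-oriented 5' end (first base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        """Genomic position of the strand-oriented 3' end (last base)."""
        return self.end - 1 if self.strand == "+" else self.start


class ReferenceGenome:
    """In-memory reference sequence: mapping contig name -> A/C/G/T/N string."""

    def __init__(self, contigs: Mapping[str, str]):
        if not contigs:
            raise ValueError("genome must contain at least one contig")
        self._seqs: dict[str, str] = {}
        self._codes: dict[str, np.ndarray] = {}
        for name, seq in contigs.items():
            if not name:
                raise ValueError("contig names must be nonempty")
            if not seq:
                raise ValueError(f"contig {name!r} has an empty sequence")
            seq = str(seq).upper()
            self._seqs[name] = seq
            self._codes[name] = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceGenome":
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(records)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="") for name, seq in self._seqs.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    @property
    def contigs(self) -> dict[str, str]:
        return dict(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    def __contains__(self, contig: str) -> bool:
        return contig in self._seqs

    def __getitem__(self, contig: str) -> str:
        return self._seqs[contig]

    def codes(self, contig: str) -> np.ndarray:
        """Sequence as a read-only uint8 byte array (fast vectorised access)."""
        return self._codes[contig]


def classify_context(
    genome: ReferenceGenome, contig: str, pos: int, strand: str
) -> str | None:
    """Classify the cytosine at (contig, pos, strand) as CG, CHG or CHH.

    Returns ``None`` (undefined) when fewer than two downstream bases exist
    on the strand or when either downstream base is not A/C/G/T.
    """
    codes = genome.codes(contig)
    if not 0 <= pos < len(codes):
        raise OutOfBoundsError(f"position {pos} outside contig {contig!r} (length {len(codes)})")
    base = codes[pos]
    if strand == "+":
        if base != _C:
            raise NotACytosineError(
                f"{contig}:{pos}(+) is {chr(base)!r}, not a cytosine"
            )
        if pos + 2 >= len(codes):
            return None
        b1, b2 = codes[pos + 1], codes[pos + 2]
    elif strand == "-":
        if base != _G:
            raise NotACytosineError(
                f"{contig}:{pos}(-) is {chr(base)!r} on forward strand, not a reverse-strand cytosine"
            )
        if pos - 2 < 0:
            return None
        b1, b2 = _COMPLEMENT[codes[pos - 1]], _COMPLEMENT[codes[pos - 2]]
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if not (_IS_ACGT[b1] and _IS_ACGT[b2]):
        return None
    if b1 == _G:
        return "CG"
    if b2 == _G:
        return "CHG"
    return "CHH"


class CytosineSite(NamedTuple):
    contig: str
    pos: int
    strand: str
    context: str


def cytosine_table(genome: ReferenceGenome, contigs: Iterable[str] | None = None) -> pd.DataFrame:
    """All cytosines with defined context on both strands, as a DataFrame.

    Columns: chrom, pos, strand, context — sorted by (chrom, pos, strand).
    Cytosines whose two downstream bases leave the contig or contain a
    non-ACGT base are excluded (context undefined).
    """
    frames = []
    names = list(contigs) if contigs is not None else list(genome.contigs)
    ctx_labels = np.array(CONTEXTS)
    for name in names:
        codes = genome.codes(name)
        n = len(codes)
        # forward strand: C with two in-bounds downstream bases
        plus = np.flatnonzero(codes == _C)
        plus = plus[plus + 2 < n]
        if plus.size:
            b1, b2 = codes[plus + 1], codes[plus + 2]
            ok = _IS_ACGT[b1] & _IS_ACGT[b2]
            plus, b1, b2 = plus[ok], b1[ok], b2[ok]
            ctx_p = np.where(b1 == _G, 0, np.where(b2 == _G, 1, 2))
        else:
            ctx_p = np.empty(0, dtype=int)
        # reverse strand: G on forward strand, downstream = revcomp of preceding bases
        minus = np.flatnonzero(codes == _G)
        minus = minus[minus >= 2]
        if minus.size:
            b1, b2 = _COMPLEMENT[codes[minus - 1]], _COMPLEMENT[codes[minus - 2]]
            ok = _IS_ACGT[b1] & _IS_ACGT[b2]
            minus, b1, b2 = minus[ok], b1[ok], b2[ok]
            ctx_m = np.where(b1 == _G, 0, np.where(b2 == _G, 1, 2))
        else:
            ctx_m = np.empty(0, dtype=int)
        pos = np.concatenate([plus, minus])
        strand = np.concatenate(
            [np.full(len(plus), "+", dtype=object), np.full(len(minus), "-", dtype=object)]
        )
        ctx = ctx_labels[np.concatenate([ctx_p, ctx_m]).astype(int)] if pos.size else np.empty(0, object)
        frame = pd.DataFrame(
            {"chrom": name, "pos": pos.astype(np.int64), "strand": strand, "context": ctx}
        )
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "pos", "strand", "context"]
    )
    out = out.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
    return out


def enumerate_cytosines(
    genome: ReferenceGenome, contigs: Iterable[str] | None = None
) -> Iterator[CytosineSite]:
    """Yield every context-defined cytosine on both strands as CytosineSite."""
    table = cytosine_table(genome, contigs)
    for row in table.itertuples(index=False):
        yield CytosineSite(row.chrom, int(row.pos), row.strand, row.context)


def _read_features_gff3(path: Path, class_map: Mapping[str, FeatureClass]) -> list[Feature]:
    import gffutils

    features: list[Feature] = []
    counter = 0
    for rec in gffutils.iterators.DataIterator(str(path)):
        fclass = class_map.get(rec.featuretype)
        if fclass is None:
            warnings.warn(
                f"skipping feature of unmapped type {rec.featuretype!r} at "
                f"{rec.seqid}:{rec.start}-{rec.end}"
            )
            continue
        counter += 1
        fid = rec.attributes.get("ID", [f"feature_{counter}"])[0]
        strand = rec.strand if rec.strand in ("+", "-") else "+"
        # GFF3 is 1-based inclusive -> 0-based half-open
        features.append(
            Feature(
                id=fid,
                feature_class=fclass,
                contig=rec.seqid,
                start=rec.start - 1,
                end=rec.end,
                strand=strand,
            )
        )
    return features


def _read_features_bed(
    path: Path,
    class_map: Mapping[str, FeatureClass],
    default_class: FeatureClass | None,
) -> list[Feature]:
    features: list[Feature] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 6:
                raise ParseError(f"expected >=6 BED columns, got {len(fields)}", lineno)
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"non-integer coordinates {start!r}/{end!r}", lineno) from exc
            fclass = class_map.get(name, default_class)
            if fclass is None:
                warnings.warn(f"skipping BED feature {name!r} with no class mapping (line {lineno})")
                continue
            features.append(
                Feature(
                    id=name,
                    feature_class=fclass,
                    contig=chrom,
                    start=start_i,
                    end=end_i,
                    strand=strand if strand in ("+", "-") else "+",
                )
            )
    return features


def read_features(
    path: str | Path,
    class_map: Mapping[str, FeatureClass] | None = None,
    default_class: FeatureClass | None = None,
) -> list[Feature]:
    """Read features from GFF3 (by extension .gff/.gff3) or 6-column BED.

    ``class_map`` maps GFF3 type values (or BED name values) onto the four
    feature classes; unmapped entries are skipped with a warning.  For BED
    input ``default_class`` is used when the name column has no mapping.
    """
    path = Path(path)
    class_map = dict(DEFAULT_CLASS_MAP if class_map is None else class_map)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_features_gff3(path, class_map)
    return _read_features_bed(path, class_map, default_class)


#: Inverse of DEFAULT_CLASS_MAP used when writing GFF3.
_CLASS_TO_TYPE = {
    FeatureClass.PROTEIN_CODING_GENE: "gene",
    FeatureClass.PSEUDOGENE: "pseudogene",
    FeatureClass.TRANSPOSABLE_ELEMENT: "transposable_element",
    FeatureClass.REPEAT: "repeat_region",
}


def write_features_gff3(features: Iterable[Feature], path: str | Path) -> None:
    """Write features as GFF3 (coordinates converted back to 1-based inclusive)."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for feat in features:
            handle.write(
                "\t".join(
                    [
                        feat.contig,
                        "seedmethylome",
                        _CLASS_TO_TYPE[feat.feature_class],
                        str(feat.start + 1),
                        str(feat.end),
                        ".",
                        feat.strand,
                        ".",
                        f"ID={feat.id}",
                    ]
                )
                + "\n"
            )
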