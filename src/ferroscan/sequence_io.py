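"""Reading and writing of sequence inputs.

Three input routes are supported, all normalised into the same in-memory
representation (:class:`SampleInput`):

* nucleotide contigs in FASTA (an external gene caller then predicts ORFs),
* protein FASTA whose headers carry gene coordinates in the ORF-caller
  dialect ``>contig_N # start # end # strand # ...``,
* GenBank flat files with translated CDS features.

Coordinates are 1-based inclusive on the forward strand.  The ordinal gene
``index`` (1-based, increasing by start coordinate along each contig) is the
unit of distance used by the neighborhood logic downstream — not nucleotide
distance.
"""

from __future__ import annotations

import re
import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass(frozen=True)
class ContigRecord:
    """One assembled contig or scaffold."""

    contig_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneCall:
    """One predicted protein-coding gene.

    ``start``/``end`` are 1-based inclusive nucleotide coordinates on the
    forward strand (``start <= end``); they are ``None`` when the input
    carried no coordinates (plain protein FASTA).  ``index`` is the ordinal
    position of the gene along its contig.
    """

    gene_id: str
    contig_id: str
    index: int
    protein: str
    start: int | None = None
    end: int | None = None
    strand: str | None = None

    def __post_init__(self):
        if self.index < 1:
            raise ValueError(f"gene index must be >= 1, got {self.index}")
        if not self.protein:
            raise ValueError(f"gene {self.gene_id}: empty protein sequence")
        if self.start is not None and self.end is not None and self.start > self.end:
            raise FormatError(f"gene {self.gene_id}: start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        """Protein length in amino acids."""
        return len(self.protein)


@dataclass
class SampleInput:
    """All gene calls for one genome/metagenome sample.

    ``orf_count`` is the total number of predicted protein-coding genes and
    is the denominator for the per-sample normalisation of category counts.
    """

    sample_id: str
    genes: list[GeneCall] = field(default_factory=list)
    orf_count: int = 0

    def __post_init__(self):
        if self.orf_count == 0:
            self.orf_count = len(self.genes)
        if self.genes and self.orf_count < len(self.genes):
            raise ValueError("orf_count smaller than number of gene calls")


def read_contigs(path: str | Path) -> list[ContigRecord]:
    """Read nucleotide contigs from a FASTA file.

    Sequences are uppercased; empty records and files without any FASTA
    record are rejected with a :class:`FormatError` naming the line.
    """
    path = Path(path)
    records: list[ContigRecord] = []
    header: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush(line_no: int):
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise FormatError(f"{path}:{header_line}: record '{header}' has an empty sequence")
        records.append(ContigRecord(contig_id=header, sequence=seq))
        header, chunks = None, []

    last = 0
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            last = i
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(i)
                stripped = line[1:].split()
                if not stripped:
                    raise FormatError(f"{path}:{i}: FASTA header with no identifier")
                header = stripped[0]
                header_line = i
            else:
                if header is None:
                    raise FormatError(f"{path}:{i}: sequence data before any FASTA header")
                chunks.append(line)
    flush(last)
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    seen = set()
    for rec in records:
        if rec.contig_id in seen:
            raise FormatError(f"{path}: duplicate contig id '{rec.contig_id}'")
        seen.add(rec.contig_id)
    return records


# ORF-caller coordinate header: ">c1_7 # 3 # 302 # 1 # extra"
_COORD_HEADER = re.compile(
    r"^(?P<id>\S+)\s*#\s*(?P<start>\S+)\s*#\s*(?P<end>\S+)\s*#\s*(?P<strand>\S+)\s*#?"
)


def _parse_int(token: str, what: str, context: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise FormatError(f"{context}: non-integer {what} '{token}'") from None


def read_protein_calls(path: str | Path, sample_id: str | None = None) -> SampleInput:
    """Read protein FASTA, parsing coordinate-bearing headers when present.

    Headers of the form ``>contig_N # start # end # strand # ...`` yield gene
    calls with coordinates and an ordinal index per contig (the contig id is
    the header id with its trailing ``_N`` ordinal stripped).  Plain headers
    yield coordinate-free genes each on its own singleton pseudo-contig, in
    which case multi-gene neighborhood rules cannot fire and a warning is
    emitted.
    """
    path = Path(path)
    sample_id = sample_id or path.stem
    raw: list[tuple[str, str, dict | None]] = []  # (gene_id, protein, coords)
    any_plain = False
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        protein = str(rec.seq).upper().replace("*", "")
        m = _COORD_HEADER.match(desc)
        if m and "#" in desc:
            gene_id = m.group("id")
            start = _parse_int(m.group("start"), "start coordinate", f"{path} header '{desc}'")
            end = _parse_int(m.group("end"), "end coordinate", f"{path} header '{desc}'")
            strand_tok = m.group("strand")
            strand = "+" if strand_tok in {"1", "+1", "+"} else "-"
            if start > end:
                raise FormatError(f"{path} header '{desc}': start {start} > end {end}")
            raw.append((gene_id, protein, {"start": start, "end": end, "strand": strand}))
        else:
            any_plain = True
            raw.append((rec.id, protein, None))
    if not raw:
        raise FormatError(f"{path}: no FASTA records found")
    if any_plain:
        warnings.warn(
            f"{path}: headers without coordinates; genes placed on singleton "
            "pseudo-contigs, multi-gene neighborhood rules cannot fire",
            stacklevel=2,
        )

    # group by contig, order by start, assign ordinal indices
    by_contig: dict[str, list[tuple[str, str, dict | None]]] = {}
    for gene_id, protein, coords in raw:
        if coords is None:
            contig = gene_id  # singleton pseudo-contig
        else:
            contig = gene_id.rsplit("_", 1)[0] if "_" in gene_id else gene_id
        by_contig.setdefault(contig, []).append((gene_id, protein, coords))

    genes: list[GeneCall] = []
    for contig, items in by_contig.items():
        items.sort(key=lambda t: (t[2]["start"] if t[2] else 0))
        for idx, (gene_id, protein, coords) in enumerate(items, start=1):
            genes.append(
                GeneCall(
                    gene_id=gene_id,
                    contig_id=contig,
                    index=idx,
                    protein=protein,
                    start=coords["start"] if coords else None,
                    end=coords["end"] if coords else None,
                    strand=coords["strand"] if coords else None,
                )
            )
    genes.sort(key=lambda g: (g.contig_id, g.index))
    return SampleInput(sample_id=sample_id, genes=genes, orf_count=len(raw))


def write_protein_calls(sample: SampleInput, path: str | Path) -> None:
    """Write gene calls as protein FASTA in the coordinate-header dialect."""
    with open(path, "w") as fh:
        for g in sample.genes:
            if g.start is not None:
                strand = "1" if g.strand == "+" else "-1"
                fh.write(f">{g.gene_id} # {g.start} # {g.end} # {strand} #\n")
            else:
                fh.write(f">{g.gene_id}\n")
            for i in range(0, len(g.protein), 60):
                fh.write(g.protein[i : i + 60] + "\n")


def read_genbank_calls(path: str | Path, sample_id: str | None = None) -> SampleInput:
    """Read translated CDS features from a GenBank flat file.

    CDS features without a translation are skipped (counted in a warning);
    a file with zero translated CDS raises :class:`FormatError`.
    """
    path = Path(path)
    sample_id = sample_id or path.stem
    genes: list[GeneCall] = []
    skipped = 0
    total_cds = 0
    for rec in SeqIO.parse(str(path), "genbank"):
        cds_feats = [f for f in rec.features if f.type == "CDS"]
        total_cds += len(cds_feats)
        entries = []
        for feat in cds_feats:
            trans = feat.qualifiers.get("translation", [None])[0]
            if not trans:
                skipped += 1
                continue
            start = int(feat.location.start) + 1  # Biopython is 0-based half-open
            end = int(feat.location.end)
            strand = "-" if feat.location.strand == -1 else "+"
            name = feat.qualifiers.get("locus_tag", feat.qualifiers.get("gene", [None]))[0]
            entries.append((start, end, strand, name, trans.upper().replace("*", "")))
        entries.sort(key=lambda t: t[0])
        for idx, (start, end, strand, name, trans) in enumerate(entries, start=1):
            gene_id = name or f"{rec.id}_{idx}"
            genes.append(
                GeneCall(
                    gene_id=gene_id,
                    contig_id=rec.id,
                    index=idx,
                    protein=trans,
                    start=start,
                    end=end,
                    strand=strand,
                )
            )
    if not genes:
        raise FormatError(f"{path}: no protein-coding features with translations")
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} CDS feature(s) without translation", stacklevel=2)
    return SampleInput(sample_id=sample_id, genes=genes, orf_count=total_cds)


def call_genes_external(
    contigs: list[ContigRecord],
    tool: str = "prodigal",
    sample_id: str = "sample",
    meta: bool = False,
) -> SampleInput:
    """Predict ORFs on contigs with an external gene caller (prodigal contract).

    The tool must write protein FASTA with coordinate headers (prodigal's
    ``-a`` output); the result is parsed via :func:`read_protein_calls`.
    """
    if not contigs:
        raise ValueError("empty contig list: nothing to predict genes on")
    exe = shutil.which(tool)
    if exe is None:
        raise RuntimeError(
            f"gene caller '{tool}' not found on PATH; supply protein FASTA or "
            "GenBank input instead"
        )
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        fasta = tmp / "contigs.fna"
        with open(fasta, "w") as fh:
            for c in contigs:
                fh.write(f">{c.contig_id}\n{c.sequence}\n")
        faa = tmp / "proteins.faa"
        cmd = [exe, "-i", str(fasta), "-a", str(faa), "-o", str(tmp / "genes.out"), "-q"]
        if meta:
            cmd += ["-p", "meta"]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(f"gene caller failed (exit {proc.returncode}): {proc.stderr[:500]}")
        sample = read_protein_calls(faa, sample_id=sample_id)
    return sample
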