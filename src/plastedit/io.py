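"""Readers and writers for every format the pipeline touches.

FASTA goes through Biopython.  GFF3 is a constrained dialect: the columns
are standard, the attributes used are ``ID`` (shared across the lines of a
multi-segment feature), ``gene`` (comma-separated list for fusions),
``pseudo=true`` and ``Is_circular=true`` on the region line.  Segment lines
of one feature appear in sense order, which keeps origin-wrapping and
minus-strand multi-segment features unambiguous and makes
``read_gff3(write_gff3(x))`` the identity.

The pileup TSV dialect is this package's own (bit-exact):

    #seqid  pos  ref  nA nC nG nT  qA qC qG qT  ins

with ``ins`` either ``.`` or semicolon-separated ``SEQ:COUNT`` entries.
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import Annotation, CircularSequence, GenomeFeature
from .pileup import Pileup, PileupColumn

PILEUP_HEADER = "#seqid\tpos\tref\tnA\tnC\tnG\tnT\tqA\tqC\tqG\tqT\tins"

_GFF_TYPES = {"CDS", "tRNA", "rRNA", "intron", "repeat_region"}


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> list[CircularSequence]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [CircularSequence(r.id, str(r.seq)) for r in records]


def write_fasta(sequences: list[CircularSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
        writer.write_file(records)


# ---------------------------------------------------------------- GFF3

def write_gff3(annotation: Annotation, path: str | Path) -> None:
    lines = ["##gff-version 3"]
    if annotation.sequence_length is not None:
        attrs = f"ID=region-{annotation.sequence_id}"
        if annotation.is_circular:
            attrs += ";Is_circular=true"
        lines.append(
            "\t".join(
                [
                    annotation.sequence_id,
                    "plastedit",
                    "region",
                    "1",
                    str(annotation.sequence_length),
                    ".",
                    "+",
                    ".",
                    attrs,
                ]
            )
        )
    for f in annotation.features:
        attrs = f"ID={f.feature_id}"
        if f.gene_names:
            attrs += ";gene=" + ",".join(f.gene_names)
        if f.pseudo:
            attrs += ";pseudo=true"
        if f.notes:
            attrs += ";Note=" + f.notes.replace(";", "%3B")
        for start, end in f.segments:
            lines.append(
                "\t".join(
                    [
                        annotation.sequence_id,
                        "plastedit",
                        f.ftype,
                        str(start),
                        str(end),
                        ".",
                        f.strand,
                        "0" if f.ftype == "CDS" else ".",
                        attrs,
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_attrs(raw: str) -> dict[str, str]:
    out = {}
    for chunk in raw.strip().split(";"):
        if chunk and "=" in chunk:
            k, v = chunk.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> Annotation:
    """Read the dialect written by :func:`write_gff3` (single sequence)."""
    seqid = None
    length = None
    circular = True
    order: list[str] = []
    pending: dict[str, dict] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        sid, _src, ftype, start, end, _score, strand, _phase, rawattrs = cols
        if seqid is None:
            seqid = sid
        elif sid != seqid:
            raise ValueError("multi-sequence GFF3 not supported by this dialect")
        attrs = _parse_attrs(rawattrs)
        if ftype == "region":
            length = int(end)
            circular = attrs.get("Is_circular", "").lower() == "true"
            continue
        if ftype not in _GFF_TYPES:
            continue
        fid = attrs.get("ID")
        if fid is None:
            raise ValueError(f"feature line without ID: {line!r}")
        seg = (int(start), int(end))
        if fid in pending:
            pending[fid]["segments"].append(seg)
        else:
            order.append(fid)
            pending[fid] = {
                "ftype": ftype,
                "strand": strand,
                "segments": [seg],
                "gene_names": attrs["gene"].split(",") if "gene" in attrs else [],
                "pseudo": attrs.get("pseudo", "").lower() == "true",
                "notes": attrs.get("Note", "").replace("%3B", ";"),
            }
    if seqid is None:
        raise ValueError(f"no records in {path}")
    features = [
        GenomeFeature(feature_id=fid, **pending[fid]) for fid in order
    ]
    return Annotation(seqid, features, sequence_length=length, is_circular=circular)


# ---------------------------------------------------------------- pileup TSV

def write_pileup(pileup: Pileup, path: str | Path) -> None:
    lines = [PILEUP_HEADER]
    for col in pileup:
        if col.insertions:
            ins = ";".join(f"{seq}:{n}" for seq, n in col.insertions)
        else:
            ins = "."
        quals = [
            f"{col.mean_phred.get(b, 0.0):g}" if col.counts[b] > 0 else "0"
            for b in "ACGT"
        ]
        lines.append(
            "\t".join(
                [
                    pileup.sequence_id,
                    str(col.position),
                    col.ref_base,
                    *(str(col.counts[b]) for b in "ACGT"),
                    *quals,
                    ins,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_pileup(path: str | Path) -> Pileup:
    text = Path(path).read_text().splitlines()
    if not text or not text[0].startswith("#seqid"):
        raise ValueError(f"{path} is not a pileup TSV (missing header)")
    pileup = None
    last_pos = 0
    for line in text[1:]:
        if not line:
            continue
        cols = line.split("\t")
        if len(cols) != 12:
            raise ValueError(f"malformed pileup line: {line!r}")
        seqid, pos, ref = cols[0], int(cols[1]), cols[2]
        if pileup is None:
            pileup = Pileup(seqid)
        elif seqid != pileup.sequence_id:
            raise ValueError("multi-sequence pileups not supported")
        if pos <= last_pos:
            raise ValueError(f"pileup positions not ascending at {pos}")
        last_pos = pos
        counts = dict(zip("ACGT", map(int, cols[3:7])))
        quals = dict(zip("ACGT", map(float, cols[7:11])))
        mean_phred = {b: quals[b] for b in "ACGT" if counts[b] > 0}
        insertions = []
        if cols[11] != ".":
            for entry in cols[11].split(";"):
                seq, n = entry.rsplit(":", 1)
                insertions.append((seq, int(n)))
        pileup.add(PileupColumn(pos, ref, counts, mean_phred, insertions))
    if pileup is None:
        raise ValueError(f"no pileup rows in {path}")
    return pileup


# ---------------------------------------------------------------- alignments

def read_alignment_fasta(path: str | Path, name: str | None = None):
    from .phylo import ProteinAlignment

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no records in {path}")
    taxa = [r.id for r in records]
    rows = [str(r.seq).upper() for r in records]
    return ProteinAlignment(name or Path(path).stem, taxa, rows)


def read_alignment_phylip(path: str | Path, name: str | None = None):
    """Relaxed (whitespace-delimited, sequential) PHYLIP."""
    from .phylo import ProteinAlignment

    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    ntax, nsites = map(int, lines[0].split()[:2])
    taxa, rows = [], []
    for ln in lines[1 : 1 + ntax]:
        parts = ln.split()
        taxa.append(parts[0])
        rows.append("".join(parts[1:]).upper())
    if len(taxa) != ntax or any(len(r) != nsites for r in rows):
        raise ValueError(f"inconsistent PHYLIP dimensions in {path}")
    return ProteinAlignment(name or Path(path).stem, taxa, rows)


def read_alignment(path: str | Path, name: str | None = None):
    """Auto-detect FASTA vs relaxed PHYLIP by the first byte."""
    first = Path(path).read_text(errors="replace").lstrip()[:1]
    if first == ">":
        return read_alignment_fasta(path, name)
    return read_alignment_phylip(path, name)
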