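"""Readers and writers for the pipeline's plain-text formats.

Conventions: BED is 0-based half-open; GFF3 is 1-based closed.  All
conversions between the two go through :func:`gff_to_bed_interval` /
:func:`bed_to_gff_interval` so the off-by-one lives in exactly one place.

Exon loci are serialized as BED12-style lines in which the chromStart/
chromEnd span the whole locus (both introns plus exon), thickStart/
thickEnd delimit the exon, and a single block covers the locus.  On the
plus strand the upstream intron is [chromStart, thickStart); on the
minus strand it is [thickEnd, chromEnd).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .clip import ClipCluster, ExonModel
from .errors import ParseError
from .silac import PEPTIDE_COLUMNS


def gff_to_bed_interval(start_1based: int, end_closed: int) -> tuple[int, int]:
    """GFF3 (1-based, closed) -> BED (0-based, half-open)."""
    return start_1based - 1, end_closed


def bed_to_gff_interval(start: int, end: int) -> tuple[int, int]:
    """BED (0-based, half-open) -> GFF3 (1-based, closed)."""
    return start + 1, end


# ---------------------------------------------------------------------------
# tabular formats


def write_peptide_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=PEPTIDE_COLUMNS)


def read_peptide_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PEPTIDE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"peptide table missing columns {sorted(missing)}", path)
    bad = df[(df["intensity_light"].isna()) & (df["intensity_heavy"].isna())]
    if not bad.empty:
        raise ParseError("peptide with both channels absent",
                         path, int(bad.index[0]) + 2)
    for col in ("intensity_light", "intensity_heavy"):
        neg = df[df[col].notna() & (df[col] < 0)]
        if not neg.empty:
            raise ParseError(f"negative {col}", path, int(neg.index[0]) + 2)
    return df


def write_spectral_counts(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("protein", "spc", "length", "nsaf") if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols)


def read_spectral_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"protein", "spc", "length"} - set(df.columns)
    if missing:
        raise ParseError(f"spectral count table missing columns {sorted(missing)}", path)
    return df


def write_delta_psi(values: dict[str, float], path) -> None:
    pd.DataFrame(
        {"exon_id": list(values), "delta_psi": list(values.values())}
    ).to_csv(path, sep="\t", index=False)


def read_delta_psi(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    missing = {"exon_id", "delta_psi"} - set(df.columns)
    if missing:
        raise ParseError(f"delta-PSI table missing columns {sorted(missing)}", path)
    return dict(zip(df["exon_id"], df["delta_psi"].astype(float)))


# ---------------------------------------------------------------------------
# BED


def write_clusters_bed(clusters: list[ClipCluster], path) -> None:
    with open(path, "w") as fh:
        for c in clusters:
            name = c.cluster_id if c.exon_id is None else f"{c.cluster_id}|{c.exon_id}"
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{name}\t0\t{c.strand}\n")


def read_clusters_bed(path) -> list[ClipCluster]:
    clusters = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError("cluster BED needs 6 columns", path, lineno)
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                s, e = int(start), int(end)
            except ValueError:
                raise ParseError("non-integer BED coordinates", path, lineno) from None
            if s >= e:
                raise ParseError(f"start >= end ({s} >= {e})", path, lineno)
            cid, _, exon_id = name.partition("|")
            clusters.append(ClipCluster(cluster_id=cid, chrom=chrom, strand=strand,
                                        start=s, end=e, exon_id=exon_id or None))
    return clusters


def write_exon_models_bed(exons: list[ExonModel], path) -> None:
    with open(path, "w") as fh:
        for e in exons:
            locus_s, locus_e = e.locus_start, e.locus_end
            psi = "" if e.delta_psi is None else f"|{e.delta_psi!r}"
            fh.write("\t".join(map(str, [
                e.chrom, locus_s, locus_e, f"{e.exon_id}{psi}", 0, e.strand,
                e.exon_start, e.exon_end, "0", 1, locus_e - locus_s, 0,
            ])) + "\n")


def read_exon_models_bed(path, seqs: dict[str, str] | None = None,
                         window: int = 100) -> list[ExonModel]:
    """Read exon loci; when ``seqs`` is given, attach the transcribed-strand
    sequence of the last ``window`` nt of each upstream intron."""
    from .simulate import reverse_complement

    exons = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 8:
                raise ParseError("exon BED needs >= 8 columns", path, lineno)
            try:
                locus_s, locus_e = int(f[1]), int(f[2])
                exon_s, exon_e = int(f[6]), int(f[7])
            except ValueError:
                raise ParseError("non-integer BED coordinates", path, lineno) from None
            if locus_s >= locus_e or exon_s >= exon_e:
                raise ParseError("start >= end", path, lineno)
            if not (locus_s < exon_s and exon_e < locus_e):
                raise ParseError("exon not strictly inside its locus", path, lineno)
            name, _, psi = f[3].partition("|")
            strand = f[5]
            if strand == "+":
                ui = (locus_s, exon_s)
                di = (exon_e, locus_e)
            else:
                ui = (exon_e, locus_e)
                di = (locus_s, exon_s)
            seq = ""
            if seqs is not None:
                chrom_seq = seqs.get(f[0])
                if chrom_seq is None:
                    raise ParseError(f"no sequence for {f[0]}", path, lineno)
                if strand == "+":
                    seq = chrom_seq[max(ui[0], ui[1] - window):ui[1]]
                else:
                    seq = reverse_complement(chrom_seq[ui[0]:min(ui[1], ui[0] + window)])
            exons.append(ExonModel(
                exon_id=name, chrom=f[0], strand=strand,
                exon_start=exon_s, exon_end=exon_e,
                upstream_intron_start=ui[0], upstream_intron_end=ui[1],
                downstream_intron_start=di[0], downstream_intron_end=di[1],
                upstream_intron_3p_seq=seq,
                delta_psi=float(psi) if psi else None))
    return exons


# ---------------------------------------------------------------------------
# FASTA / JSON


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"duplicate FASTA identifier {rec.id!r}", path)
        seqs[rec.id] = str(rec.seq)
    return seqs


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
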