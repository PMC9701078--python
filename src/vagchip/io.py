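"""Shared readers/writers and run configuration.

FASTA/FASTQ go through Bio.SeqIO (Phred+33), wrapped so malformed records
are reported with their record number and approximate line. Sequence paths
ending in ``.gz`` are transparently decompressed. Tables are TSV via pandas.

The plain-text config dialect is INI (configparser): sections [geometry],
[transport], [solver]; keys are the dataclass field names of ChipGeometry /
TransportParams (bench units encoded in the names, e.g. ``length_mm``,
``Q_apical_uL_per_h``); unknown keys are rejected.
"""

from __future__ import annotations

import configparser
import gzip
import hashlib
import logging
from dataclasses import fields
from pathlib import Path
from typing import IO, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chip_transport import ChipGeometry, TransportParams
from .strain_composition import MarkerGeneSet, QualityRead, StrainGeneSet

logger = logging.getLogger("vagchip")

__all__ = [
    "read_fasta", "write_fasta", "read_fastq", "write_fastq",
    "read_tsv", "write_tsv", "read_strain_gene_dir", "markers_to_fasta",
    "markers_from_fasta", "read_config", "file_checksum", "setup_logging",
]


def _open_text(path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[tuple[str, str]]:
    """(id, uppercase sequence) pairs from a FASTA file (.gz ok)."""
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq).upper())
                for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(path, records: list[tuple[str, str]]) -> None:
    with _open_text(path, "wt") as fh:
        SeqIO.write((SeqRecord(Seq(seq), id=rid, description="")
                     for rid, seq in records), fh, "fasta")


def read_fastq(path) -> list[QualityRead]:
    """Reads with Phred+33 qualities; malformed records raise with their
    record number and approximate line."""
    out: list[QualityRead] = []
    with _open_text(path) as fh:
        parser = SeqIO.parse(fh, "fastq")
        n = 0
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed FASTQ record {n + 1} "
                    f"(around line {4 * n + 1}): {exc}") from exc
            n += 1
            out.append(QualityRead(
                rec.id, str(rec.seq).upper(),
                tuple(rec.letter_annotations["phred_quality"])))
    return out


def write_fastq(path, reads: Iterator[QualityRead] | list[QualityRead]) -> None:
    def to_rec(r: QualityRead) -> SeqRecord:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        return rec

    with _open_text(path, "wt") as fh:
        SeqIO.write((to_rec(r) for r in reads), fh, "fastq")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_strain_gene_dir(directory) -> list[StrainGeneSet]:
    """One FASTA per strain (file stem = strain id) -> gene sets."""
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir()
                   if p.suffix in (".fa", ".fasta", ".fna")
                   or p.name.endswith((".fa.gz", ".fasta.gz", ".fna.gz")))
    if not paths:
        raise FileNotFoundError(f"no FASTA files in {directory}")
    out = []
    for p in paths:
        stem = p.name.split(".")[0]
        out.append(StrainGeneSet(strain_id=stem,
                                 genes=tuple(read_fasta(p))))
    return out


def markers_to_fasta(path, markers: list[MarkerGeneSet]) -> None:
    """Markers as FASTA with ids ``<strain_id>|<gene_id>``."""
    records = [(f"{ms.strain_id}|{gid}", seq)
               for ms in markers for gid, seq in ms.markers]
    write_fasta(path, records)


def markers_from_fasta(path) -> list[MarkerGeneSet]:
    by_strain: dict[str, list[tuple[str, str]]] = {}
    for rid, seq in read_fasta(path):
        if "|" not in rid:
            raise ValueError(
                f"{path}: marker id {rid!r} is not '<strain>|<gene>'")
        strain, gid = rid.split("|", 1)
        by_strain.setdefault(strain, []).append((gid, seq))
    return [MarkerGeneSet(strain_id=s, markers=tuple(genes))
            for s, genes in sorted(by_strain.items())]


def _from_section(cls, section: configparser.SectionProxy | dict, where: str):
    valid = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, raw in section.items():
        if key not in valid:
            raise KeyError(
                f"unknown key {key!r} in [{where}]; valid keys: "
                f"{sorted(valid)}")
        kwargs[key] = float(raw)
    return cls(**kwargs)


def read_config(path) -> tuple[ChipGeometry, TransportParams, dict]:
    """Parse an INI config into (geometry, transport params, solver options).

    All sections are optional; omitted keys keep their documented defaults.
    [solver] accepts nx, ny, tol, max_iter, t_end_min, dt_s.
    """
    cp = configparser.ConfigParser()
    cp.optionxform = str          # keys are case-sensitive field names
    read = cp.read(path)
    if not read:
        raise FileNotFoundError(path)
    known = {"geometry", "transport", "solver"}
    unknown = set(cp.sections()) - known
    if unknown:
        raise KeyError(f"unknown config sections: {sorted(unknown)}")
    geometry = (_from_section(ChipGeometry, cp["geometry"], "geometry")
                if cp.has_section("geometry") else ChipGeometry())
    transport = (_from_section(TransportParams, cp["transport"], "transport")
                 if cp.has_section("transport") else TransportParams())
    solver_valid = {"nx": int, "ny": int, "tol": float, "max_iter": int,
                    "t_end_min": float, "dt_s": float}
    solver: dict = {}
    if cp.has_section("solver"):
        for key, raw in cp["solver"].items():
            if key not in solver_valid:
                raise KeyError(f"unknown key {key!r} in [solver]; valid keys: "
                               f"{sorted(solver_valid)}")
            solver[key] = solver_valid[key](float(raw))
    return geometry, transport, solver


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s")
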