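"""File I/O for the pipeline's plain-text interchange formats.

All coordinate columns are 1-based closed intervals (UniProt chain
convention); every writer states this in a leading comment line where the
format allows comments.  FASTA is written via Biopython, wrapped at 60
columns.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalog import ChainAnnotation, PeptideRecord
from .synthdata import SerologyCohort, IpmsBundle, spec_to_dict

__all__ = [
    "write_catalog_tsv",
    "write_annotations_tsv",
    "write_ebs_tsv",
    "read_ebs_tsv",
    "write_metadata_tsv",
    "write_fasta",
    "read_fasta",
    "write_surface_list",
    "read_surface_list",
    "write_intensity_tables",
    "read_intensity_tables",
    "write_serology_cohort",
    "write_ipms_bundle",
]


def write_catalog_tsv(catalog: Sequence[PeptideRecord], path) -> None:
    pd.DataFrame(
        {
            "peptide_id": [p.peptide_id for p in catalog],
            "accession": [p.accession for p in catalog],
            "start": [p.start for p in catalog],
            "end": [p.end for p in catalog],
            "strain": [p.strain for p in catalog],
        }
    ).to_csv(path, sep="\t", index=False)


def write_annotations_tsv(annotations: Sequence[ChainAnnotation], path) -> None:
    pd.DataFrame(
        {
            "accession": [a.accession for a in annotations],
            "chain_name": [a.chain_name.value for a in annotations],
            "start": [a.start for a in annotations],
            "end": [a.end for a in annotations],
            "ce1_start": [a.ce1_start for a in annotations],
            "ce1_end": [a.ce1_end for a in annotations],
        }
    ).to_csv(path, sep="\t", index=False)


def write_ebs_tsv(ebs: pd.DataFrame, path) -> None:
    """EBS matrix: individuals in rows, peptide ids as header columns."""
    ebs.to_csv(path, sep="\t", index=True, float_format="%.6g")


def read_ebs_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_metadata_tsv(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=True, float_format="%.6g")


def write_fasta(sequences: Mapping[str, str], path) -> None:
    """Write sequences as FASTA wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_surface_list(ids: Iterable[str], path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in ids))


def read_surface_list(path) -> list[str]:
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]


def write_intensity_tables(tables: Mapping[str, pd.DataFrame], outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for line, tab in tables.items():
        tab.to_csv(outdir / f"intensity_{line}.tsv", sep="\t",
                   index=True, float_format="%.6g")


def read_intensity_tables(indir) -> dict[str, pd.DataFrame]:
    out = {}
    for f in sorted(Path(indir).glob("intensity_*.tsv")):
        line = f.stem.removeprefix("intensity_")
        out[line] = pd.read_csv(f, sep="\t", index_col=0)
    return out


def _write_spec_sidecar(spec, path) -> None:
    if spec is not None:
        Path(path).write_text(json.dumps(spec_to_dict(spec), indent=2) + "\n")


def write_serology_cohort(cohort: SerologyCohort, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_catalog_tsv(cohort.catalog, outdir / "peptide_catalog.tsv")
    write_annotations_tsv(cohort.annotations, outdir / "annotations.tsv")
    write_ebs_tsv(cohort.ebs, outdir / "ebs_matrix.tsv")
    write_metadata_tsv(cohort.metadata, outdir / "clinical_metadata.tsv")
    _write_spec_sidecar(cohort.spec, outdir / "cohort_spec.json")


def write_ipms_bundle(bundle: IpmsBundle, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_intensity_tables(bundle.inputs.tables, outdir)
    write_fasta(bundle.sequences, outdir / "candidate_sequences.fasta")
    write_surface_list(bundle.surface_list, outdir / "surface_proteome.txt")
    _write_spec_sidecar(bundle.spec, outdir / "mimicry_spec.json")
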