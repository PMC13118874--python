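"""Readers and writers for the pipeline's on-disk formats.

All tabular files are tab-separated with a header row. Two Broad-ecosystem
formats are supported for signature exchange:

* GCT 1.3 — ``#1.3`` version line, a dims line ``nrows ncols nrowmeta ncolmeta``,
  then a header block and the data matrix. Row/column metadata blocks are
  round-tripped.
* GMT — one gene set per line: ``name<TAB>description<TAB>gene1<TAB>gene2...``.

The counts dialect places a ``gene_length`` column between the gene id index
and the first sample column.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from woundsig.containers import (
    CountExperiment,
    ExpressionMatrix,
    WoundSignature,
    ReferenceSignatureSet,
    as_integer_counts,
    check_design_labels,
)

# ---------------------------------------------------------------------------
# counts + sample metadata


def write_counts(experiment: CountExperiment, path: str | Path) -> None:
    out = pd.DataFrame(index=experiment.counts.index)
    out.index.name = "gene_id"
    out["gene_length"] = experiment.gene_lengths
    for col in experiment.counts.columns:
        out[col] = experiment.counts[col]
    out.to_csv(path, sep="\t")


def read_counts(counts_path: str | Path, meta_path: str | Path) -> CountExperiment:
    raw = pd.read_csv(counts_path, sep="\t", index_col=0)
    if "gene_length" not in raw.columns:
        raise ValueError(f"{counts_path}: missing gene_length column")
    lengths = raw["gene_length"].astype(np.int64)
    counts = raw.drop(columns="gene_length")
    counts = pd.DataFrame(
        as_integer_counts(counts.values), index=counts.index, columns=counts.columns
    )
    samples = read_sample_metadata(meta_path)
    return CountExperiment(counts=counts, gene_lengths=lengths, samples=samples)


def write_sample_metadata(samples: pd.DataFrame, path: str | Path) -> None:
    out = samples.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    required = {"timepoint", "intervention"}
    if not required <= set(samples.columns):
        raise ValueError(f"{path}: sample metadata needs columns {sorted(required)}")
    check_design_labels(samples)
    return samples


# ---------------------------------------------------------------------------
# expression matrices


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a normalized matrix; the header comment records provenance."""
    with open(path, "w") as fh:
        fh.write(f"# normalization_tag={matrix.normalization_tag}\n")
        if matrix.scale_factors is not None:
            factors = ",".join(
                f"{s}:{f:.10g}" for s, f in matrix.scale_factors.items()
            )
            fh.write(f"# scale_factors={factors}\n")
        matrix.values.to_csv(fh, sep="\t", index_label="gene_id")


def read_expression(path: str | Path, samples: pd.DataFrame) -> ExpressionMatrix:
    tag = "TPM"
    factors = None
    with open(path) as fh:
        text = fh.read()
    body_lines = []
    for line in text.splitlines():
        if line.startswith("# normalization_tag="):
            tag = line.split("=", 1)[1].strip()
        elif line.startswith("# scale_factors="):
            pairs = line.split("=", 1)[1].strip()
            factors = pd.Series(
                {k: float(v) for k, v in (p.split(":") for p in pairs.split(","))}
            )
        else:
            body_lines.append(line)
    values = pd.read_csv(_io.StringIO("\n".join(body_lines)), sep="\t", index_col=0)
    return ExpressionMatrix(
        values=values, normalization_tag=tag, samples=samples, scale_factors=factors
    )


# ---------------------------------------------------------------------------
# GCT 1.3


def write_gct(reference: ReferenceSignatureSet, path: str | Path) -> None:
    """Write the z-score matrix as GCT 1.3 with a ``pert_id`` column-metadata row."""
    z = reference.z
    pert_ids = [reference.perturbagen_of(c) for c in z.columns]
    with open(path, "w") as fh:
        fh.write("#1.3\n")
        fh.write(f"{z.shape[0]}\t{z.shape[1]}\t0\t1\n")
        fh.write("id\t" + "\t".join(map(str, z.columns)) + "\n")
        fh.write("pert_id\t" + "\t".join(pert_ids) + "\n")
        for gene, row in zip(z.index, z.values):
            fh.write(str(gene) + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def read_gct(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a GCT 1.3 file.

    Returns ``(matrix, col_meta)`` where ``matrix`` is gene x signature and
    ``col_meta`` is indexed by signature id (empty if the file has no
    column-metadata rows). Row-metadata columns are parsed and discarded.
    """
    with open(path) as fh:
        version = fh.readline().strip()
        if version not in ("#1.3", "#1.2"):
            raise ValueError(f"{path}: not a GCT file (version line {version!r})")
        dims = fh.readline().split()
        if version == "#1.2":
            n_rows, n_cols = int(dims[0]), int(dims[1])
            n_rmeta, n_cmeta = 0, 0
        else:
            n_rows, n_cols, n_rmeta, n_cmeta = map(int, dims[:4])
        header = fh.readline().rstrip("\n").split("\t")
        sig_ids = header[1 + n_rmeta :]
        if len(sig_ids) != n_cols:
            raise ValueError(
                f"{path}: dims line declares {n_cols} columns, header has {len(sig_ids)}"
            )
        cmeta_rows = {}
        for _ in range(n_cmeta):
            parts = fh.readline().rstrip("\n").split("\t")
            cmeta_rows[parts[0]] = parts[1 + n_rmeta :]
        genes, data = [], []
        for _ in range(n_rows):
            parts = fh.readline().rstrip("\n").split("\t")
            genes.append(parts[0])
            data.append([float(v) for v in parts[1 + n_rmeta :]])
    matrix = pd.DataFrame(np.asarray(data), index=genes, columns=sig_ids)
    col_meta = pd.DataFrame(cmeta_rows, index=sig_ids)
    return matrix, col_meta


def read_reference(
    gct_path: str | Path,
    sig_meta_path: str | Path | None = None,
    pert_meta_path: str | Path | None = None,
) -> ReferenceSignatureSet:
    """Assemble a ReferenceSignatureSet from a GCT plus annotation TSVs.

    If no sig_meta TSV is given, the GCT's embedded ``pert_id`` column-metadata
    row is required.
    """
    z, col_meta = read_gct(gct_path)
    if sig_meta_path is not None:
        sig_meta = pd.read_csv(sig_meta_path, sep="\t", index_col=0, dtype=str)
    elif "pert_id" in col_meta.columns:
        sig_meta = col_meta[["pert_id"]]
    else:
        raise ValueError("no signature metadata: supply a TSV or embed pert_id in the GCT")
    if pert_meta_path is not None:
        pert_meta = pd.read_csv(pert_meta_path, sep="\t", index_col=0, dtype=str)
    else:
        pert_meta = pd.DataFrame(
            index=pd.Index(sorted(set(sig_meta["pert_id"])), name="pert_id")
        )
    return ReferenceSignatureSet(z=z, sig_meta=sig_meta, pert_meta=pert_meta)


# ---------------------------------------------------------------------------
# GMT


def write_gmt(sets: dict[str, list[str]], path: str | Path, descriptions: dict | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *map(str, genes)]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = [g for g in parts[2:] if g]
    return sets


def write_signature_gmt(signature: WoundSignature, path: str | Path) -> None:
    """Two sets per timepoint: ``<tp>_WsDEG_up`` and ``<tp>_WsDEG_down``."""
    write_gmt(
        {
            f"{signature.timepoint}_WsDEG_up": signature.up_genes,
            f"{signature.timepoint}_WsDEG_down": signature.down_genes,
        },
        path,
        descriptions={
            f"{signature.timepoint}_WsDEG_up": "wound-only up-regulated",
            f"{signature.timepoint}_WsDEG_down": "wound-only down-regulated",
        },
    )


def read_signature_gmt(path: str | Path, timepoint: str) -> WoundSignature:
    sets = read_gmt(path)
    up_key, down_key = f"{timepoint}_WsDEG_up", f"{timepoint}_WsDEG_down"
    if up_key not in sets or down_key not in sets:
        raise ValueError(f"{path}: expected sets {up_key} and {down_key}")
    return WoundSignature(timepoint=timepoint, up_genes=sets[up_key], down_genes=sets[down_key])
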