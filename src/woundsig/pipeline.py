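"""End-to-end orchestration: normalize -> DEG -> signature -> connect ->
prioritize -> enrich, with a manifest for reproducibility auditing.

Every stage writes its artifacts under the configured output directory; the
manifest records SHA-256 hashes of all inputs and outputs plus the seed and
package version, so identical configuration and seed must reproduce identical
hashes. Stage failures abort with the stage name attached.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from woundsig import __version__
from woundsig.containers import TIMEPOINTS, WoundSignature
from woundsig import differential_expression as de
from woundsig import io as wio
from woundsig import normalization
from woundsig import signatures as sig
from woundsig import connectivity
from woundsig import prioritization
from woundsig import enrichment


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run; thresholds default to the study's."""

    counts: str
    metadata: str
    reference_gct: str | None = None
    sig_meta: str | None = None
    pert_meta: str | None = None
    gene_sets_gmt: str | None = None
    out_dir: str = "pipeline_out"
    seed: int = 0
    deg_log2fc: float = de.DEG_LOG2FC
    deg_p: float = de.DEG_P
    top_log2fc: float = de.TOP_DEG_LOG2FC
    top_p: float = de.TOP_DEG_P
    top_k: int = prioritization.DEFAULT_TOP_K
    freq_min_exclusive: int = prioritization.FREQ_MIN_EXCLUSIVE
    fisher_alpha: float = prioritization.FISHER_ALPHA
    enrich_min_count_exclusive: int = enrichment.ENRICH_MIN_COUNT_EXCLUSIVE
    enrich_p: float = enrichment.ENRICH_P
    kappa: float = enrichment.KAPPA_THRESHOLD
    tag_cap: int = sig.DEFAULT_TAG_CAP
    pseudocount: float = 1.0
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known}
        kwargs["extra"] = {k: v for k, v in data.items() if k not in known}
        return cls(**kwargs)


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"pipeline stage {stage!r} failed: {detail}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def emit(path: Path) -> Path:
        artifacts.append(path)
        return path

    # --- normalize -------------------------------------------------------
    try:
        experiment = wio.read_counts(config.counts, config.metadata)
        expr = normalization.normalize(experiment, pseudocount=config.pseudocount)
        wio.write_expression(expr, emit(out / "expression_log2_tpm_uq.tsv"))
    except StageError:
        raise
    except Exception as exc:
        raise StageError("normalize", str(exc)) from exc

    # --- differential expression ----------------------------------------
    try:
        degs = {}
        for tp in TIMEPOINTS:
            degs[tp] = {}
            for iv in ("N", "A", "AW"):
                table = de.test_contrast(expr, de.ContrastSpec(tp, iv))
                table = de.call_degs(
                    table,
                    deg_log2fc=config.deg_log2fc,
                    deg_p=config.deg_p,
                    top_log2fc=config.top_log2fc,
                    top_p=config.top_p,
                )
                degs[tp][iv] = table
                de.write_deg_table(table, emit(out / f"deg_{tp}_{iv}.tsv"))
    except Exception as exc:
        raise StageError("deg", str(exc)) from exc

    # --- signature extraction + descriptive exports ----------------------
    try:
        signatures: dict[str, WoundSignature] = {}
        for tp in TIMEPOINTS:
            ws = sig.extract_wsdegs(degs[tp]["AW"], degs[tp]["N"], degs[tp]["A"])
            signatures[tp] = ws
            wio.write_signature_gmt(ws, emit(out / f"wsdeg_{tp}.gmt"))
            pd.Series(ws.provenance).to_csv(
                emit(out / f"wsdeg_{tp}_provenance.tsv"), sep="\t", header=False
            )
            sig.volcano_data(degs[tp]["AW"]).to_csv(
                emit(out / f"volcano_{tp}_AW.tsv"), sep="\t", index_label="gene_id"
            )
            if ws.genes:
                z, flags = sig.signature_matrices(expr, ws)
                z.to_csv(emit(out / f"heatmap_z_{tp}.tsv"), sep="\t", index_label="gene_id")
        corr, mds = sig.sample_similarity(expr)
        corr.to_csv(emit(out / "sample_pearson.tsv"), sep="\t", index_label="sample_id")
        mds.to_csv(emit(out / "sample_mds.tsv"), sep="\t", index_label="sample_id")
    except Exception as exc:
        raise StageError("signature", str(exc)) from exc

    # --- connectivity + prioritization -----------------------------------
    candidates: dict[str, pd.DataFrame] = {}
    if config.reference_gct:
        try:
            reference = wio.read_reference(
                config.reference_gct, config.sig_meta, config.pert_meta
            )
            for tp in TIMEPOINTS:
                if not signatures[tp].up_genes or not signatures[tp].down_genes:
                    continue
                scores = connectivity.score_all(
                    signatures[tp], reference, tag_cap=config.tag_cap
                )
                scores.to_csv(
                    emit(out / f"connectivity_{tp}.tsv"), sep="\t", index_label="signature_id"
                )
                table = prioritization.rank_candidates(
                    scores,
                    reference.pert_meta,
                    k=config.top_k,
                    freq_min_exclusive=config.freq_min_exclusive,
                    fisher_alpha=config.fisher_alpha,
                )
                candidates[tp] = table
                table.to_csv(emit(out / f"candidates_{tp}.tsv"), sep="\t")
            if candidates:
                union = prioritization.aggregate_across_conditions(candidates)
                union.to_csv(emit(out / "candidates_union.tsv"), sep="\t")
        except StageError:
            raise
        except Exception as exc:
            raise StageError("connect/prioritize", str(exc)) from exc

    # --- enrichment -------------------------------------------------------
    if config.gene_sets_gmt:
        try:
            collections = wio.read_gmt(config.gene_sets_gmt)
            universe = set(expr.values.index.astype(str))
            for tp in TIMEPOINTS:
                genes = signatures[tp].genes
                if not genes:
                    continue
                result = enrichment.run_ora(
                    genes,
                    collections,
                    universe,
                    min_count_exclusive=config.enrich_min_count_exclusive,
                    p_threshold=config.enrich_p,
                    kappa_threshold=config.kappa,
                )
                result.table.to_csv(emit(out / f"enrichment_{tp}.tsv"), sep="\t")
        except Exception as exc:
            raise StageError("enrich", str(exc)) from exc

    # --- summary + manifest ----------------------------------------------
    summary = summarize(degs, signatures)
    summary.to_csv(emit(out / "summary.tsv"), sep="\t", index=False)

    inputs = [
        p
        for p in (
            config.counts,
            config.metadata,
            config.reference_gct,
            config.sig_meta,
            config.pert_meta,
            config.gene_sets_gmt,
        )
        if p
    ]
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: v for k, v in asdict(config).items() if k not in ("extra",)
        },
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
        "outputs": {p.name: _sha256(p) for p in sorted(artifacts)},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def summarize(degs: dict, signatures: dict[str, WoundSignature]) -> pd.DataFrame:
    """Per-timepoint accounting: DEG counts, up/down split, WsDEG bookkeeping.

    The identity ``n_wsdeg + n_excluded_overlap = n_deg_aw`` holds by
    construction and is re-checked here.
    """
    rows = []
    for tp, ws in signatures.items():
        aw = degs[tp]["AW"].table
        n_deg = int(aw["is_deg"].sum())
        prov = ws.provenance
        if prov and prov["n_wsdeg"] + prov["n_excluded_overlap"] != n_deg:
            raise AssertionError(
                f"{tp}: WsDEG bookkeeping violated "
                f"({prov['n_wsdeg']} + {prov['n_excluded_overlap']} != {n_deg})"
            )
        rows.append(
            {
                "timepoint": tp,
                "n_deg_aw": n_deg,
                "n_up": int((aw["direction"] == "up").sum()),
                "n_down": int((aw["direction"] == "down").sum()),
                "n_wsdeg": len(ws.genes),
                "n_excluded_overlap": prov.get("n_excluded_overlap", 0),
            }
        )
    return pd.DataFrame(rows)
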