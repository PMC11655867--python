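"""On-disk formats and the end-to-end pipeline.

Matrices are stored probes × samples (NanoString convention, first
column the probe id); in memory everything is samples × probes.  Every
pipeline stage writes its artifact plus a JSON provenance record with
the inputs, parameters, seed and package version.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cartography import (
    build_cartography,
    classify_table,
    fm_index,
    sentinel_cluster_diagnosis,
)
from .discover import ModuleSet, build_module_set
from .exceptions import ConfigurationError, DataError
from .match import TreatmentTargetMap, cohort_match_summary, match_table
from .normalize import RawCounts, normalize_counts
from .score import fit_score_table, score_and_call
from .simulate import (
    DISEASE_ACTIVE_MODULES,
    DISEASE_DOMINANT_MODULE,
    default_config,
    generate_cohort,
)


# ----------------------------------------------------------------------
# readers / writers
# ----------------------------------------------------------------------

def write_counts(raw: RawCounts, counts_path, annotation_path, metadata_path=None) -> None:
    out = raw.counts.T
    out.index.name = "probe_id"
    out.to_csv(counts_path, sep="\t")
    raw.annotation.to_csv(annotation_path, sep="\t")
    if metadata_path is not None:
        raw.metadata.to_csv(metadata_path, sep="\t")


def read_counts(counts_path, annotation_path, metadata_path=None) -> RawCounts:
    """Read a probes × samples TSV/CSV plus its probe annotation."""
    sep = "\t" if str(counts_path).endswith((".tsv", ".txt")) else None
    try:
        mat = pd.read_csv(counts_path, sep=sep, index_col=0, engine="python")
    except pd.errors.ParserError as exc:
        raise DataError(f"malformed counts file {counts_path}: {exc}") from exc
    if mat.isna().any().any():
        bad = mat.columns[mat.isna().any()][0]
        raise DataError(f"missing/ragged values in counts file (column {bad!r})")
    ann = pd.read_csv(annotation_path, sep="\t", index_col=0)
    meta = (
        pd.read_csv(metadata_path, sep="\t", index_col=0).fillna("")
        if metadata_path is not None
        else pd.DataFrame(index=mat.columns)
    )
    return RawCounts(counts=mat.T, annotation=ann, metadata=meta)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    out = matrix.T
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0).T


def write_provenance(path, stage: str, params: dict, inputs: dict | None = None) -> None:
    record = {
        "stage": stage,
        "package": "immunocarto",
        "version": __version__,
        "inputs": inputs or {},
        "params": params,
    }
    Path(path).write_text(json.dumps(record, indent=2, default=str))


# ----------------------------------------------------------------------
# pipeline
# ----------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Configuration of the full run; paths may be omitted when simulating."""

    outdir: str = "immunocarto_out"
    counts: str | None = None
    annotation: str | None = None
    metadata: str | None = None
    modules: str | None = None       # pre-built ModuleSet JSON; else discover
    simulate: bool = True
    panel: str = "extended"
    seed: int = 0
    direction: str = "corrective"
    fc_threshold: float = 1.0
    p_threshold: float = 0.01
    use_adjusted: bool = True
    n_boot: int = 1000
    alpha: float = 0.05
    gene_set: str = "module"
    knn: int = 5
    matching_rule: str = "argmax"
    use_embedding: bool = True
    sim_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("fc_threshold", "p_threshold", "alpha"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not self.simulate:
            for name in ("counts", "annotation"):
                path = getattr(self, name)
                if path is None:
                    raise ConfigurationError(f"{name} path required when not simulating")
                if not Path(path).exists():
                    raise ConfigurationError(f"{name} path {path!r} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))


def run_pipeline(config: PipelineConfig) -> Path:
    """simulate?→normalize→discover|load→score→cartography→evaluate→match.

    Returns the output directory; every stage leaves its artifact and a
    provenance JSON there.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        sim = default_config(panel=config.panel, seed=config.seed, **config.sim_overrides)
        raw, truth = generate_cohort(sim)
        write_counts(raw, out / "counts.tsv", out / "annotation.tsv", out / "metadata.tsv")
        (out / "truth.json").write_text(
            json.dumps(
                {
                    "disease": truth.disease.to_dict(),
                    "module_genes": truth.module_genes,
                    "dominant": {k: list(v) for k, v in truth.dominant.items()},
                    "depth": truth.depth.to_dict(),
                },
                indent=2,
            )
        )
        write_provenance(out / "simulate.provenance.json", "simulate", asdict(sim) | {"panel": config.panel})
    else:
        raw = read_counts(config.counts, config.annotation, config.metadata)

    norm = normalize_counts(raw, direction=config.direction)
    write_matrix(norm.data, out / "normalized.tsv")
    pd.DataFrame(
        {"positive_factor": norm.positive_factors, "housekeeping_factor": norm.housekeeping_factors}
    ).to_csv(out / "factors.tsv", sep="\t")
    write_provenance(out / "normalize.provenance.json", "normalize", {"direction": config.direction})

    labels = raw.metadata["disease"] if "disease" in raw.metadata else None
    if labels is None:
        raise ConfigurationError("metadata must carry a 'disease' column")
    roles = raw.metadata.get("role", pd.Series("sentinel", index=raw.metadata.index))
    sentinel_mask = roles.isin(["sentinel"])
    sent_norm = norm.data.loc[sentinel_mask[sentinel_mask].index]
    sent_labels = labels[sentinel_mask]

    if config.modules:
        modules = ModuleSet.load_json(config.modules)
    else:
        modules = build_module_set(
            sent_norm,
            sent_labels,
            fc_threshold=config.fc_threshold,
            p_threshold=config.p_threshold,
            use_adjusted=config.use_adjusted,
        )
    modules.save_json(out / "modules.json")
    write_provenance(
        out / "discover.provenance.json", "discover",
        {"fc_threshold": config.fc_threshold, "p_threshold": config.p_threshold,
         "use_adjusted": config.use_adjusted, "loaded": bool(config.modules)},
    )

    from .score import module_score

    disease_positive = {
        d: tuple(m for m in mods if m in modules.modules)
        for d, mods in DISEASE_ACTIVE_MODULES.items()
    }
    usable = [
        m for m in modules
        if len(modules[m]) > 0
        and sent_labels.isin(
            [d for d, mods in disease_positive.items() if m in mods]
        ).sum() >= 3
    ]
    modules_fit = ModuleSet({m: modules[m] for m in usable}, modules.provenance)
    table = fit_score_table(sent_norm, modules_fit, sent_labels, disease_positive)
    act = score_and_call(norm.data, modules_fit, table, n_boot=config.n_boot,
                         alpha=config.alpha, seed=config.seed)
    module_score(norm.data, modules).to_csv(out / "scores.tsv", sep="\t")
    act.to_frame().to_csv(out / "activations.tsv", sep="\t")
    write_provenance(out / "score.provenance.json", "score",
                     {"n_boot": config.n_boot, "alpha": config.alpha, "seed": config.seed})

    carto = build_cartography(
        sent_norm, sent_labels, modules, gene_set=config.gene_set,
        seed=config.seed, use_embedding=config.use_embedding,
        expected_module=DISEASE_DOMINANT_MODULE,
    )
    predicted = sentinel_cluster_diagnosis(carto)
    fm = fm_index(predicted, sent_labels)
    evaluation = {"sentinel_clustering_fm": fm, "n_sentinels": int(sentinel_mask.sum())}

    query_ids = roles.index[~sentinel_mask]
    if len(query_ids):
        method = "embedding" if config.use_embedding else "pearson"
        diagnoses = classify_table(
            carto, norm.data.loc[query_ids], k=config.knn, method=method
        )
        assigned = {sid: diagnoses[str(sid)].assigned for sid in query_ids}
        pd.Series(assigned, name="assigned").to_csv(out / "classification.tsv", sep="\t")
        evaluation["query_fm"] = fm_index(
            [assigned[s] for s in query_ids], labels[query_ids].tolist()
        )
    (out / "evaluation.json").write_text(json.dumps(evaluation, indent=2))
    write_provenance(out / "cartography.provenance.json", "cartography",
                     {"gene_set": config.gene_set, "seed": config.seed, "knn": config.knn})

    treatments = raw.metadata.get("treatment")
    if treatments is not None and treatments.astype(str).str.len().gt(0).any():
        treated = treatments[treatments.astype(str).str.len() > 0].index
        tmap = TreatmentTargetMap(known_modules=modules.modules)
        results = match_table(
            act.activations.loc[treated], treatments[treated], tmap,
            rule=config.matching_rule,
            responses=raw.metadata.get("response"),
        )
        pd.DataFrame([asdict(r) for r in results]).to_csv(out / "match.tsv", sep="\t", index=False)
        (out / "match_summary.json").write_text(json.dumps(cohort_match_summary(results), indent=2))
        write_provenance(out / "match.provenance.json", "match", {"rule": config.matching_rule})

    return out
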