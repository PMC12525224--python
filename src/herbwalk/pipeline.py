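"""End-to-end orchestration: build → diffuse → prioritize → enrich → mechanisms.

A single :class:`PipelineConfig` (YAML-serializable) drives the run. All
tabular outputs are TSV, graphs GraphML + SIF, and a manifest records every
parameter plus content hashes, so a rerun with the same config and inputs
reproduces identical files. Any stage failure removes the files written so
far and re-raises with the stage name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .diffusion import (
    DEFAULT_CLASS_WEIGHTS,
    WalkParams,
    build_transition_model,
    compute_diffusion_profile,
)
from .enrichment import (
    DISEASE_PATHWAY_WHITELIST,
    enrich,
    filter_disease_pathways,
    results_to_frame,
)
from .exceptions import HerbwalkError
from .io import read_gmt
from .mechanism import export_subnetwork, extract_mechanism
from .network import (
    DiseaseGeneSet,
    HerbCatalog,
    MultiscaleNetwork,
    assemble_network,
    attach_entity,
    filter_herbs_min_ingredients,
    load_edge_list,
)
from .prioritization import (
    default_background,
    rank_compounds,
    rank_herbs,
    score_herbs,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline inputs, thresholds and walk parameters.

    The prioritization defaults are the study constants this package
    implements: ≥3 target-bearing ingredients per herb, top 50 targets by
    simple path count, overlap p < 0.05, ≥5 active compounds, top 10 herbs,
    and k = 20 mechanism nodes per profile.
    """

    # input paths
    ppi: str = "ppi.tsv"
    protein_function: str = "protein_function.tsv"
    function_hierarchy: str = "function_hierarchy.tsv"
    herb_compound: str = "herb_compound.tsv"
    compound_target: str = "compound_target.tsv"
    disease: str = "disease.gmt"
    enrichment_library: str | None = None

    # walk
    restart_prob: float = 0.5
    class_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS))
    tol: float = 1e-10
    max_iter: int = 500

    # prioritization thresholds (study constants)
    p_threshold: float = 0.05
    min_ingredients: int = 3
    min_active_compounds: int = 5
    top_targets: int = 50
    top_n: int = 10
    k: int = 20
    correlation_method: str = "pearson"

    # enrichment
    n_background_queries: int = 200

    outdir: str = "herbwalk_out"
    seed: int = 0

    def walk_params(self) -> WalkParams:
        return WalkParams(self.restart_prob, dict(self.class_weights),
                          self.tol, self.max_iter)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise HerbwalkError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run all stages; returns a map of output names to paths.

    Outputs: ``herb_ranking.tsv``, ``compounds_<herb>.tsv`` per ranked herb,
    ``enrichment.tsv`` + ``disease_pathways.tsv`` when a library is
    configured, ``mechanism_<compound>.graphml``/``.sif`` for each ranked
    herb's top compound, ``manifest.json`` and ``run.log``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logging.getLogger("herbwalk").addHandler(handler)
    stage = "load"
    try:
        params = config.walk_params()
        ppi = load_edge_list(config.ppi, "ppi")
        pf = load_edge_list(config.protein_function, "protein_function")
        fh = load_edge_list(config.function_hierarchy, "function_hierarchy")
        catalog = HerbCatalog.from_tsv(config.herb_compound,
                                       config.compound_target)
        disease = DiseaseGeneSet.from_file(config.disease)

        stage = "build"
        net = assemble_network(ppi, pf, fh)
        catalog = filter_herbs_min_ingredients(catalog, config.min_ingredients)

        stage = "diffuse"
        scratch = net.copy()
        attach_entity(scratch, disease.disease_id, "disease", disease.genes)
        model = build_transition_model(scratch, params)
        disease_profile = compute_diffusion_profile(
            model, disease.disease_id, params)

        stage = "rank-herbs"
        background = default_background(net, catalog, disease)
        scores = score_herbs(net, catalog, disease_profile, disease, params,
                             background, config.top_targets,
                             config.correlation_method)
        ranking = rank_herbs(scores, config.p_threshold,
                             config.min_active_compounds, config.top_n)
        rank_path = outdir / "herb_ranking.tsv"
        ranking.to_csv(rank_path, sep="\t", index=False, float_format="%.6g")
        written.append(rank_path)

        stage = "rank-compounds"
        compound_tables = {}
        for herb in ranking["entity"]:
            table = rank_compounds(herb, net, catalog, disease_profile,
                                   disease, params, background,
                                   config.p_threshold,
                                   config.correlation_method)
            path = outdir / f"compounds_{herb}.tsv"
            table.to_csv(path, sep="\t", index=False, float_format="%.6g")
            written.append(path)
            compound_tables[herb] = table

        stage = "enrich"
        if config.enrichment_library:
            library = read_gmt(config.enrichment_library)
            query = set()
            for herb in ranking["entity"]:
                query |= catalog.herb_targets(herb)
            bg = frozenset().union(*library.values()) | query
            results = enrich(query, library, bg,
                             config.n_background_queries, config.seed)
            enr_path = outdir / "enrichment.tsv"
            results_to_frame(results).to_csv(enr_path, sep="\t", index=False,
                                             float_format="%.6g")
            written.append(enr_path)
            wl_path = outdir / "disease_pathways.tsv"
            results_to_frame(
                filter_disease_pathways(results, DISEASE_PATHWAY_WHITELIST)
            ).to_csv(wl_path, sep="\t", index=False, float_format="%.6g")
            written.append(wl_path)

        stage = "mechanism"
        for herb, table in compound_tables.items():
            if table.empty:
                continue
            compound = str(table.iloc[0]["entity"])
            mech_net = net.copy()
            attach_entity(mech_net, disease.disease_id, "disease",
                          disease.genes)
            attach_entity(mech_net, compound, "compound",
                          catalog.targets_of(compound))
            mech_model = build_transition_model(mech_net, params)
            cprof = compute_diffusion_profile(mech_model, compound, params)
            dprof = compute_diffusion_profile(mech_model,
                                              disease.disease_id, params)
            sub = extract_mechanism(mech_net, cprof, dprof, config.k)
            for fmt in ("graphml", "sif"):
                path = outdir / f"mechanism_{compound}.{fmt}"
                export_subnetwork(sub, path, fmt)
                written.append(path)

        stage = "manifest"
        manifest = {
            "package": "herbwalk",
            "version": __version__,
            "seed": config.seed,
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "outputs": {p.name: _sha256(p) for p in sorted(written)},
        }
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2,
                                            sort_keys=True) + "\n")
        written.append(manifest_path)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise HerbwalkError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logging.getLogger("herbwalk").removeHandler(handler)
        handler.close()

    out = {p.name: p for p in written}
    out["run.log"] = log_path
    return out
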