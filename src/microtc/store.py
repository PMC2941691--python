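"""Flat-file artifact store and the offline pipeline driver.

The store replaces a database at desk scale: every derived artifact is a
diffable text file under a fixed layout,

    <root>/experiments/<id>/{matrix.tsv, design.yaml, normalized.tsv,
                             annotations.tsv, tcs.tsv, tc_stats/, summaries.tsv,
                             manifests/}
    <root>/relations/   <root>/index/   <root>/plots/

and each stage records a manifest (config hash + input checksums) so
re-runs skip stages whose inputs have not changed.  The pipeline proper
is deterministic; randomness exists only in the synthetic generator and
is seeded through the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from pathlib import Path

import pandas as pd
import yaml

from . import preprocess, relations as rel, search
from .annotation import TranscriptDb, map_probe_sets, read_probe_table, write_annotation_tsv
from .design import Design, FactorDecl, read_design, write_design
from .errors import PipelineError, UnreplicatedError
from .matrix import ExpressionMatrix, read_expression_matrix
from .plots import PlotStyle, ma_points_for_tc, render_ma_plot
from .synth import Spike, SyntheticDesignSpec, generate_experiment, ice1_like_spec
from .tc import compute_tc_stats, enumerate_tcs, resolve_declared_tcs, write_tc_stats_tsv

log = logging.getLogger(__name__)

STAGES = ("ingest", "annotate", "normalize", "tc_stats", "relations", "index", "plots")


class ArtifactStore:
    """Fixed-layout directory of pipeline artifacts."""

    def __init__(self, root):
        self.root = Path(root)

    def experiment_dir(self, experiment_id: str) -> Path:
        return self.root / "experiments" / experiment_id

    def manifest_path(self, experiment_id: str, stage: str) -> Path:
        return self.experiment_dir(experiment_id) / "manifests" / f"{stage}.json"

    def read_manifest(self, experiment_id: str, stage: str) -> dict | None:
        p = self.manifest_path(experiment_id, stage)
        if not p.exists():
            return None
        return json.loads(p.read_text())

    def write_manifest(self, experiment_id: str, stage: str, manifest: dict) -> None:
        p = self.manifest_path(experiment_id, stage)
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(json.dumps(manifest, sort_keys=True, indent=1))

    def tc_tables(self, experiment_id: str) -> dict[str, pd.DataFrame]:
        d = self.experiment_dir(experiment_id) / "tc_stats"
        tables = {}
        for f in sorted(d.glob("*.tsv")):
            tables[f.stem] = pd.read_csv(f, sep="\t", index_col="feature_id")
        return tables


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _stage_current(store, eid, stage, cfg_hash, inputs: list[Path], outputs: list[Path]) -> bool:
    man = store.read_manifest(eid, stage)
    if man is None or man.get("config_hash") != cfg_hash:
        return False
    if man.get("inputs") != {str(p): _sha256(p) for p in inputs if p.exists()}:
        return False
    return all(Path(o).exists() for o in man.get("outputs", []))


def _finish_stage(store, eid, stage, cfg_hash, inputs: list[Path], outputs: list[Path], counts: dict):
    store.write_manifest(
        eid,
        stage,
        {
            "stage": stage,
            "config_hash": cfg_hash,
            "inputs": {str(p): _sha256(p) for p in inputs if p.exists()},
            "outputs": [str(o) for o in outputs],
            "counts": counts,
        },
    )
    log.info("stage %s: %s", stage, counts)


def _spec_from_config(synth_cfg: dict, seed: int | None) -> SyntheticDesignSpec:
    synth_cfg = dict(synth_cfg)
    if seed is not None:
        synth_cfg.setdefault("seed", seed)
    preset = synth_cfg.pop("preset", None)
    spikes = tuple(
        Spike(feature=s["feature"], where=dict(s["where"]), delta=float(s["delta"]))
        for s in synth_cfg.pop("spikes", [])
    )
    if preset == "ice1":
        return ice1_like_spec(spikes=spikes, **synth_cfg)
    factors = tuple(
        FactorDecl(name=f["name"], levels=tuple(f["levels"]), control_level=f["control_level"])
        for f in synth_cfg.pop("factors")
    )
    return SyntheticDesignSpec(factors=factors, spikes=spikes, **synth_cfg)


def run_pipeline(config, store_root, seed: int | None = None, force: bool = False) -> ArtifactStore:
    """Execute ingest → annotate → normalize → tc-stats → relations → index → plots.

    ``config`` is a YAML path or a dict.  Stages are skipped when their
    manifest shows unchanged config and inputs (``force`` recomputes).
    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    store = ArtifactStore(store_root)
    eid = str(config.get("experiment_id", "experiment"))
    edir = store.experiment_dir(eid)
    edir.mkdir(parents=True, exist_ok=True)

    matrix_path = edir / "matrix.tsv"
    design_path = edir / "design.yaml"
    normalized_path = edir / "normalized.tsv"
    annotations_path = edir / "annotations.tsv"
    tcs_path = edir / "tcs.tsv"
    summaries_path = edir / "summaries.tsv"
    stats_dir = edir / "tc_stats"

    # ---- ingest ------------------------------------------------------------
    stage = "ingest"
    try:
        cfg = {"synth": config.get("synth"), "inputs": config.get("inputs"), "seed": seed}
        ch = _config_hash(cfg)
        src_inputs: list[Path] = []
        if config.get("inputs"):
            src_inputs = [Path(config["inputs"]["matrix"]), Path(config["inputs"]["design"])]
        if force or not _stage_current(store, eid, stage, ch, src_inputs, [matrix_path, design_path]):
            if config.get("synth"):
                spec = _spec_from_config(config["synth"], seed)
                generate_experiment(spec, outdir=str(edir))
                design = read_design(design_path)
                matrix = read_expression_matrix(matrix_path)
            else:
                inputs = config["inputs"]
                matrix = read_expression_matrix(
                    inputs["matrix"],
                    orientation=inputs.get("orientation", "row-features"),
                    scale=inputs.get("scale", "log2"),
                )
                design = read_design(inputs["design"], chip_ids=matrix.chip_ids)
                matrix.write_tsv(matrix_path)
                write_design(design, design_path)
            _finish_stage(
                store, eid, stage, ch, src_inputs, [matrix_path, design_path],
                {"features": matrix.shape[0], "chips": matrix.shape[1], "sample_sets": len(design.sample_sets)},
            )
        else:
            log.info("stage %s: up to date, skipped", stage)
    except UnreplicatedError as exc:
        raise PipelineError(stage, str(exc)) from exc
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, f"{type(exc).__name__}: {exc}") from exc

    matrix = read_expression_matrix(matrix_path)
    design = read_design(design_path, chip_ids=matrix.chip_ids)

    # ---- annotate (optional) ----------------------------------------------
    stage = "annotate"
    ann_cfg = config.get("annotation")
    if ann_cfg:
        try:
            ch = _config_hash(ann_cfg)
            inputs = [Path(ann_cfg["fasta"]), Path(ann_cfg["probes"])]
            if force or not _stage_current(store, eid, stage, ch, inputs, [annotations_path]):
                db = TranscriptDb.from_fasta(ann_cfg["fasta"], ann_cfg.get("annotation_tsv"))
                probe_sets = read_probe_table(ann_cfg["probes"])
                records = map_probe_sets(probe_sets, db, min_probes=int(ann_cfg.get("min_probes", 9)))
                write_annotation_tsv(records, annotations_path)
                _finish_stage(store, eid, stage, ch, inputs, [annotations_path],
                              {"probe_sets": len(records), "mapped": sum(r.mapped for r in records)})
            else:
                log.info("stage %s: up to date, skipped", stage)
        except Exception as exc:
            raise PipelineError(stage, f"{type(exc).__name__}: {exc}") from exc

    # ---- normalize ---------------------------------------------------------
    stage = "normalize"
    try:
        norm_cfg = {"normalize": config.get("normalize", True),
                    "probe_membership": (config.get("inputs") or {}).get("probe_membership")}
        ch = _config_hash(norm_cfg)
        if force or not _stage_current(store, eid, stage, ch, [matrix_path], [normalized_path]):
            m = matrix.to_log2()
            if norm_cfg["normalize"]:
                m = preprocess.quantile_normalize(m)
            if norm_cfg["probe_membership"]:
                memb = pd.read_csv(norm_cfg["probe_membership"], sep="\t", dtype=str)
                mapping = dict(zip(memb["probe_id"], memb["probe_set_id"]))
                m = preprocess.median_polish_summarize(m, mapping)
            m.write_tsv(normalized_path)
            _finish_stage(store, eid, stage, ch, [matrix_path], [normalized_path],
                          {"features": m.shape[0], "chips": m.shape[1]})
        else:
            log.info("stage %s: up to date, skipped", stage)
    except Exception as exc:
        raise PipelineError(stage, f"{type(exc).__name__}: {exc}") from exc

    normalized = read_expression_matrix(normalized_path)

    # ---- tc_stats (+ per-sample-set summaries) ------------------------------
    stage = "tc_stats"
    try:
        stats_cfg = config.get("stats", {})
        qc_cfg = config.get("qc", {})
        ch = _config_hash({"stats": stats_cfg, "qc": qc_cfg})
        tcs = enumerate_tcs(design.sample_sets, design.factors) + resolve_declared_tcs(design)
        seen, uniq = set(), []
        for tc in tcs:
            if tc.tc_id not in seen:
                seen.add(tc.tc_id)
                uniq.append(tc)
        tcs = uniq
        outputs = [tcs_path, summaries_path] + [stats_dir / f"{tc.tc_id}.tsv" for tc in tcs]
        if force or not _stage_current(store, eid, stage, ch, [normalized_path, design_path], outputs):
            stats_dir.mkdir(parents=True, exist_ok=True)
            for tc in tcs:
                table = compute_tc_stats(normalized, tc, equal_var=bool(stats_cfg.get("equal_var", False)))
                write_tc_stats_tsv(table, stats_dir / f"{tc.tc_id}.tsv")
            pd.DataFrame(
                [
                    {"tc_id": tc.tc_id, "name": tc.name, "treatment": tc.treatment.name,
                     "control": tc.control.name, "differing_factor": tc.differing_factor,
                     "description": tc.description}
                    for tc in tcs
                ]
            ).to_csv(tcs_path, sep="\t", index=False)
            summaries = [
                preprocess.sampleset_stats(normalized, s,
                                           cv_definition=qc_cfg.get("cv_definition", "sd_over_mean"),
                                           cv_scale=qc_cfg.get("cv_scale", "log2"))
                for s in design.sample_sets
            ]
            preprocess.write_summary_tsv(summaries, summaries_path,
                                         threshold=float(qc_cfg.get("threshold", preprocess.DEFAULT_CV_THRESHOLD)))
            _finish_stage(store, eid, stage, ch, [normalized_path, design_path], outputs,
                          {"tcs": len(tcs), "features": normalized.shape[0]})
        else:
            log.info("stage %s: up to date, skipped", stage)
    except UnreplicatedError as exc:
        raise PipelineError(stage, str(exc)) from exc
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, f"{type(exc).__name__}: {exc}") from exc

    tables = store.tc_tables(eid)

    # ---- relations ---------------------------------------------------------
    stage = "relations"
    try:
        rel_cfg = config.get("relations", {})
        ch = _config_hash(rel_cfg)
        rel_dir = store.root / "relations"
        axis = rel_cfg.get("axis", "tcs")
        refs = rel_cfg.get("refs", "all")
        universe = rel.RatioUniverse.from_tc_tables(tables)
        ref_ids = (universe.tc_ids if axis == "tcs" else universe.gene_ids) if refs == "all" else list(refs)
        outputs = [rel_dir / f"{axis}_{ref}.tsv" for ref in ref_ids]
        dep_inputs = [tcs_path]
        if force or not _stage_current(store, eid, stage, ch, dep_inputs, outputs):
            rel_dir.mkdir(parents=True, exist_ok=True)
            n_rel = 0
            import warnings as _warnings

            for ref in ref_ids:
                with _warnings.catch_warnings():
                    # refs with empty regulation sets legitimately yield no
                    # relations during a bulk run; the empty TSV records that
                    _warnings.simplefilter("ignore", UserWarning)
                    records = rel.rank_relations(
                        universe, ref, axis=axis,
                        fold_min=float(rel_cfg.get("fold_min", rel.DEFAULT_FOLD_MIN)),
                        p_max=float(rel_cfg.get("p_max", rel.DEFAULT_P_MAX)),
                        min_overlap=int(rel_cfg.get("min_overlap", rel.DEFAULT_MIN_OVERLAP)),
                    )
                rel.relations_to_frame(records).to_csv(rel_dir / f"{axis}_{ref}.tsv", sep="\t", index=False,
                                                       float_format="%.10g")
                n_rel += len(records)
            _finish_stage(store, eid, stage, ch, dep_inputs, outputs, {"refs": len(ref_ids), "relations": n_rel})
        else:
            log.info("stage %s: up to date, skipped", stage)
    except Exception as exc:
        raise PipelineError(stage, f"{type(exc).__name__}: {exc}") from exc

    # ---- index -------------------------------------------------------------
    stage = "index"
    try:
        ch = _config_hash({"index": config.get("index", True)})
        idx_path = store.root / "index" / "index.json"
        if force or not _stage_current(store, eid, stage, ch, [tcs_path, design_path], [idx_path]):
            docs = _build_docs(eid, design, normalized, tcs_path, annotations_path)
            idx = search.build_index(docs)
            idx_path.parent.mkdir(parents=True, exist_ok=True)
            idx.save(idx_path)
            _finish_stage(store, eid, stage, ch, [tcs_path, design_path], [idx_path], {"docs": len(docs)})
        else:
            log.info("stage %s: up to date, skipped", stage)
    except Exception as exc:
        raise PipelineError(stage, f"{type(exc).__name__}: {exc}") from exc

    # ---- plots -------------------------------------------------------------
    stage = "plots"
    try:
        plot_cfg = config.get("plots", {})
        ch = _config_hash(plot_cfg)
        plot_dir = store.root / "plots"
        tc_sel = plot_cfg.get("tcs", "all")
        tc_ids = list(tables) if tc_sel == "all" else list(tc_sel)
        gene_ids = list(plot_cfg.get("genes", []))
        style = PlotStyle(width_px=int(plot_cfg.get("width_px", 480)),
                          height_px=int(plot_cfg.get("height_px", 480)))
        outputs = [plot_dir / f"tc_{t}.png" for t in tc_ids] + [plot_dir / f"gene_{g}.png" for g in gene_ids]
        if force or not _stage_current(store, eid, stage, ch, [tcs_path], outputs):
            plot_dir.mkdir(parents=True, exist_ok=True)
            for t in tc_ids:
                pts = ma_points_for_tc(t, tables[t])
                render_ma_plot(pts, style, str(plot_dir / f"tc_{t}.png"),
                               str(plot_dir / f"tc_{t}.overlay.jsonl"))
            if gene_ids:
                from .plots import ma_points_for_gene

                for g in gene_ids:
                    pts = ma_points_for_gene(g, tables)
                    render_ma_plot(pts, style, str(plot_dir / f"gene_{g}.png"),
                                   str(plot_dir / f"gene_{g}.overlay.jsonl"))
            _finish_stage(store, eid, stage, ch, [tcs_path], outputs,
                          {"tc_plots": len(tc_ids), "gene_plots": len(gene_ids)})
        else:
            log.info("stage %s: up to date, skipped", stage)
    except Exception as exc:
        raise PipelineError(stage, f"{type(exc).__name__}: {exc}") from exc

    return store


def _build_docs(eid: str, design: Design, matrix: ExpressionMatrix, tcs_path: Path, annotations_path: Path):
    docs = [
        search.SearchDoc(
            doc_id=f"experiment:{eid}",
            doc_type="experiment",
            fields={"experiment_title": design.title, "experiment_description": design.description},
        )
    ]
    ann: dict[str, tuple[str, str]] = {}
    if annotations_path.exists():
        tab = pd.read_csv(annotations_path, sep="\t", dtype=str).fillna("")
        ann = {r["probe_set_id"]: (r["symbol"], r["description"]) for _, r in tab.iterrows()}
    for g in matrix.feature_ids:
        symbol, desc = ann.get(g, ("", ""))
        docs.append(
            search.SearchDoc(
                doc_id=f"gene:{g}",
                doc_type="gene",
                fields={"gene_identifier": g, "gene_symbol": symbol, "gene_annotation": desc},
            )
        )
    tcs = pd.read_csv(tcs_path, sep="\t").fillna("")
    for _, row in tcs.iterrows():
        docs.append(
            search.SearchDoc(
                doc_id=f"tc:{row['tc_id']}",
                doc_type="tc",
                fields={"tc_name": row["name"], "tc_description": row["description"]},
            )
        )
    return docs


def query_views(store: ArtifactStore, view: str, entity_id: str, experiment_id: str | None = None):
    """Query the store along the three display axes.

    * ``gene``: all T/C rows for the gene, sorted by |LOG2R| descending.
    * ``tc``: the full per-gene stats table of one T/C.
    * ``experiment``: metadata dict with sample sets and T/C definitions.
    """
    if view == "experiment":
        eid = entity_id
        design = read_design(store.experiment_dir(eid) / "design.yaml")
        tcs = pd.read_csv(store.experiment_dir(eid) / "tcs.tsv", sep="\t").fillna("")
        return {
            "experiment_id": eid,
            "title": design.title,
            "description": design.description,
            "sample_sets": {
                s.name: {"members": [m.sample_id for m in s.members], "profile": dict(s.profile)}
                for s in design.sample_sets
            },
            "tcs": tcs.to_dict(orient="records"),
        }
    exps = [experiment_id] if experiment_id else sorted(
        p.name for p in (store.root / "experiments").iterdir() if p.is_dir()
    )
    if view == "tc":
        for eid in exps:
            path = store.experiment_dir(eid) / "tc_stats" / f"{entity_id}.tsv"
            if path.exists():
                return pd.read_csv(path, sep="\t", index_col="feature_id")
        raise PipelineError("view", f"unknown T/C {entity_id!r}")
    if view == "gene":
        rows = []
        for eid in exps:
            for tc_id, table in store.tc_tables(eid).items():
                if entity_id in table.index:
                    row = table.loc[entity_id].to_dict()
                    row["tc_id"] = tc_id
                    row["experiment_id"] = eid
                    rows.append(row)
        if not rows:
            raise PipelineError("view", f"unknown gene {entity_id!r}")
        df = pd.DataFrame(rows).set_index("tc_id")
        return df.reindex(df["log2r"].abs().sort_values(ascending=False).index)
    raise PipelineError("view", f"unknown view {view!r}")
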