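"""End-to-end orchestration: mine -> score -> network -> extend -> enrich.

Every stage reads and writes plain files so stages are independently
runnable and testable; ``run_pipeline`` chains them and emits a manifest
with a SHA-256 content hash per artifact. All stage outputs are pure
functions of their inputs plus the configured seed, so a rerun with the
same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

from . import corpus as corpus_io
from . import enrichment as go
from . import lexicon as lex
from . import network as net
from . import regin as rg
from . import stats
from . import synthetic as syn
from .errors import ConfigurationError, PipelineError
from .ner import annotate_corpus, write_mentions_tsv

log = logging.getLogger("mirlitnet")


@dataclass(frozen=True)
class PipelineConfig:
    corpus: Path
    mirna_lexicon: Path
    disease_lexicon: Path
    outdir: Path
    regins: tuple[Path, ...] = ()
    obo: Path | None = None
    annotations: Path | None = None
    alpha: float = 0.05
    top_k: int = 20
    seed_set_size: int = 5
    overlap_threshold: int = 3
    direction: str = "targets"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must be in (0,1), got {self.alpha}")
        if self.overlap_threshold < 1:
            raise ConfigurationError("overlap_threshold must be >= 1")
        if self.top_k < 1:
            raise ConfigurationError("top_k must be >= 1")
        if self.seed_set_size < 1:
            raise ConfigurationError("seed_set_size must be >= 1")


_PATH_KEYS = {"corpus", "mirna_lexicon", "disease_lexicon", "outdir",
              "obo", "annotations"}
_INT_KEYS = {"top_k", "seed_set_size", "overlap_threshold", "seed"}


def parse_config(path: str | Path) -> PipelineConfig:
    """Parse a ``key = value`` config file (``#`` comments, comma lists)."""
    values: dict[str, object] = {}
    base = Path(path).parent
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigurationError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key in _PATH_KEYS:
                values[key] = base / value
            elif key == "regins":
                values[key] = tuple(base / p.strip() for p in value.split(",") if p.strip())
            elif key in _INT_KEYS:
                values[key] = int(value)
            elif key == "alpha":
                values[key] = float(value)
            elif key == "direction":
                values[key] = value
            else:
                raise ConfigurationError(f"{path}:{lineno}: unknown key {key!r}")
    missing = {"corpus", "mirna_lexicon", "disease_lexicon", "outdir"} - set(values)
    if missing:
        raise ConfigurationError(f"{path}: missing required keys {sorted(missing)}")
    return PipelineConfig(**values)  # type: ignore[arg-type]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _partition(seq: Sequence[str], size: int) -> dict[str, list[str]]:
    return {
        f"set-{i // size + 1}": list(seq[i:i + size])
        for i in range(0, len(seq), size)
    }


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run all stages; returns the manifest (artifact name -> sha256)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def emit(path: Path) -> Path:
        artifacts.append(path)
        return path

    # -- mine ---------------------------------------------------------------
    try:
        records = corpus_io.read_corpus(config.corpus)
        mirna_lexicon = lex.load_mirna_lexicon(config.mirna_lexicon)
        groups = lex.load_disease_lexicon(config.disease_lexicon)
        annotated = annotate_corpus(records, mirna_lexicon, groups)
        write_mentions_tsv(annotated, emit(outdir / "mentions.tsv"))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("mine", str(exc)) from exc
    n_mentions = sum(
        len(a.mirna_spans) + len(a.disease_spans) for a in annotated.abstracts
    )
    log.info("mine: %d abstracts, %d mentions", len(records), n_mentions)

    # -- score --------------------------------------------------------------
    if not records:
        raise PipelineError("score", "empty corpus")
    try:
        scored = stats.score_all_pairs(annotated, alpha=config.alpha)
        ranked = stats.top_k(scored, k=max(len(scored), 1))
        stats.write_associations_tsv(ranked, emit(outdir / "associations.tsv"))
        top = ranked[: config.top_k]
        stats.write_associations_tsv(top, emit(outdir / "associations_top.tsv"))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("score", str(exc)) from exc
    log.info("score: %d pairs, %d significant",
             len(scored), sum(r.significant for r in scored))

    # -- network ------------------------------------------------------------
    try:
        graph = net.build_bipartite(ranked)
        graph.graph["label"] = "miRNA-disease association network"
        for fmt, name in (("graphml", "bipartite.graphml"),
                          ("xgmml", "bipartite.xgmml"),
                          ("edge_tsv", "bipartite_edges.tsv")):
            net.export_network(graph, fmt, emit(outdir / name))
    except Exception as exc:
        raise PipelineError("network", str(exc)) from exc
    log.info("network: %d nodes, %d edges",
             graph.number_of_nodes(), graph.number_of_edges())

    # -- extend -------------------------------------------------------------
    extnet = None
    if config.regins:
        try:
            regins = [
                rg.load_regin(p, "xgmml" if p.suffix == ".xgmml" else "tsv")
                for p in config.regins
            ]
            acc = lex.accession_map(mirna_lexicon)
            top_names = list(dict.fromkeys(r.mirna_id for r in top))
            seeds = [acc[m] for m in top_names if m in acc]
            skipped = [m for m in top_names if m not in acc]
            if skipped:
                log.warning("extend: no accession for %s; skipped", skipped)
            if not seeds:
                raise PipelineError(
                    "extend", "no top miRNA has a miRBase accession"
                )
            extnet = rg.extend_network(seeds, regins, direction=config.direction)
            filtered = rg.overlap_threshold(extnet, config.overlap_threshold)
            seed_sets = _partition(seeds, config.seed_set_size)
            tables = rg.mti_accounting(extnet, seed_sets)
            tables["summary"].to_csv(
                emit(outdir / "mti_summary.tsv"), sep="\t", index=False
            )
            filtered_tables = rg.mti_accounting(filtered, seed_sets)
            filtered_tables["defined_targets"].to_csv(
                emit(outdir / "defined_targets.tsv"), sep="\t", index=False
            )
            names = lex.name_by_accession(mirna_lexicon)
            rg.write_targets_tsv(filtered, emit(outdir / "mirna_targets.tsv"), names)
            ext_graph = filtered.to_graph()
            ext_graph.graph["label"] = "extended regulatory network"
            net.export_network(ext_graph, "graphml", emit(outdir / "extended.graphml"))
            net.export_network(ext_graph, "xgmml", emit(outdir / "extended.xgmml"))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("extend", str(exc)) from exc
        log.info("extend: %d seeds, %d edges pre-filter, %d post-filter",
                 len(seeds), len(extnet.visible_edges), len(filtered.visible_edges))

    # -- enrich -------------------------------------------------------------
    if config.obo is not None and config.annotations is not None:
        if extnet is None:
            raise PipelineError("enrich", "enrichment requires the extend stage")
        try:
            dag = go.parse_obo(config.obo)
            annot = go.load_annotations(config.annotations)
            query = sorted(filtered.defined_targets())
            if not query:
                raise PipelineError(
                    "enrich", "no defined targets after overlap filtering"
                )
            rows = go.enrich(query, annot, dag, alpha=config.alpha)
            go.write_enrichment_tsv(rows, emit(outdir / "enrichment.tsv"))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("enrich", str(exc)) from exc
        log.info("enrich: %d tested terms, %d significant",
                 len(rows), sum(r.significant for r in rows))

    manifest = {p.name: _sha256(p) for p in artifacts}
    manifest_path = outdir / "manifest.json"
    with manifest_path.open("w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


@dataclass(frozen=True)
class SimulationConfig:
    """Fixture parameters for `simulate`; corpus settings ride along."""

    corpus: syn.CorpusConfig = field(default_factory=syn.CorpusConfig)
    n_regin_sources: int = 3
    n_targets: int = 30
    n_all_source_targets: int = 6
    n_go_terms: int = 10
    seed: int = 0


def simulate(outdir: str | Path, sim: SimulationConfig | None = None) -> dict[str, Path]:
    """Write a complete synthetic fixture directory consumable by
    :func:`run_pipeline` (corpus, lexicons, RegINs, OBO, annotations,
    ground truth, and a ready config file)."""
    sim = sim or SimulationConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cc = replace(sim.corpus, seed=sim.seed)
    records, truth = syn.generate_corpus(cc)
    files: dict[str, Path] = {}

    files["corpus"] = outdir / "corpus.jsonl"
    corpus_io.write_corpus(records, files["corpus"])

    # fixture lexicons restricted to the generator's vocabulary
    entries = [
        lex.MirnaLexiconEntry(m, f"MIMAT8{i + 1:06d}")
        for i, m in enumerate(sorted(cc.mirna_ids))
    ]
    files["mirna_lexicon"] = outdir / "mirna_lexicon.tsv"
    lex.write_mirna_lexicon(
        entries, files["mirna_lexicon"],
        header_comment="synthetic fixture lexicon; accessions are synthetic",
    )
    groups = [g for g in lex.default_disease_groups() if g.name in cc.disease_groups]
    files["disease_lexicon"] = outdir / "disease_lexicon.tsv"
    lex.write_disease_lexicon(groups, files["disease_lexicon"])

    # RegINs: a block of targets present in every source, the rest random
    accessions = [e.accession for e in entries]
    rng_spec_seed = sim.seed + 1_000_003
    from random import Random

    rng = Random(rng_spec_seed)
    source_names = [f"RegIN-{c}" for c in ("A", "B", "C")][: sim.n_regin_sources]
    overlap_spec: dict[str, frozenset[str]] = {}
    for j in range(sim.n_targets):
        gene = f"G{j + 1:04d}"
        if j < sim.n_all_source_targets:
            overlap_spec[gene] = frozenset(source_names)
        else:
            size = rng.randint(1, len(source_names))
            overlap_spec[gene] = frozenset(rng.sample(source_names, size))
    regins = syn.generate_regins(
        sim.n_regin_sources, accessions, sim.n_targets,
        overlap_spec=overlap_spec, seed=rng_spec_seed, source_names=source_names,
    )
    regin_paths = []
    for regin in regins:
        stem = regin.source_name.lower().replace("-", "_")
        tsv = outdir / f"{stem}.tsv"
        rg.write_regin_tsv(regin, tsv)
        rg.write_regin_xgmml(regin, outdir / f"{stem}.xgmml")
        regin_paths.append(tsv)
        files[regin.source_name] = tsv

    # GO fixture over the RegIN target universe; the planted enriched term
    # annotates the all-source target block that survives overlap filtering
    genes = sorted({t for r in regins for _, t in r.edges})
    enriched_genes = sorted(overlap_spec)[: sim.n_all_source_targets]
    dag, annot = syn.generate_go_fixture(
        n_genes=len(genes), n_terms=sim.n_go_terms,
        enriched_genes=[g for g in enriched_genes if g in genes],
        seed=sim.seed + 2_000_003, genes=genes,
    )
    files["obo"] = outdir / "go.obo"
    go.write_obo(dag, files["obo"])
    files["annotations"] = outdir / "annotations.tsv"
    go.write_annotations(annot, files["annotations"])

    files["ground_truth"] = outdir / "ground_truth.json"
    with files["ground_truth"].open("w", encoding="utf-8", newline="\n") as fh:
        json.dump(
            {
                "planted_pairs": sorted(map(list, truth.planted_pairs)),
                "abstracts": [
                    {"id": aid, "mirnas": list(ms), "groups": list(gs)}
                    for aid, ms, gs in truth.abstracts
                ],
            },
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")

    files["config"] = outdir / "pipeline.cfg"
    with files["config"].open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("# generated fixture configuration\n")
        fh.write("corpus = corpus.jsonl\n")
        fh.write("mirna_lexicon = mirna_lexicon.tsv\n")
        fh.write("disease_lexicon = disease_lexicon.tsv\n")
        fh.write(f"regins = {', '.join(p.name for p in regin_paths)}\n")
        fh.write("obo = go.obo\nannotations = annotations.tsv\n")
        fh.write("outdir = results\n")
        fh.write(f"seed = {sim.seed}\n")
    return files
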