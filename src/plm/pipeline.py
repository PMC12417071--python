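"""End-to-end pipeline orchestration and run provenance.

A run executes: synthesize (or load) a corpus -> preprocess/tokenize ->
stage-1 masked-value pretraining -> stage-2 annotation pretraining ->
zero-shot annotation of the held-out split -> integration benchmark ->
attention network for one cell -> gene programs. Every artifact lands in the
run directory and is listed, with content hashes, in manifest.json alongside
the hash of the fully-serialized configuration.

Pipeline defaults are desk-scale (a 2,000-cell calibration corpus and a
small encoder) so a complete run finishes in minutes on one CPU; the
published-scale architecture defaults live in :class:`plm.model.ModelConfig`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import annotate as ann
from . import grn as grn_mod
from . import programs as prog_mod
from .io import BinConfig, bin_expression, build_vocabulary, normalize_log, select_hvgs
from .model import ModelConfig, save_checkpoint
from .synthetic import calibration_config, generate_corpus, split
from .tokenize import encode_corpus
from .train import (TrainConfig, evaluate_masked_mse, pretrain_annotation,
                    pretrain_mlm)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    seed: int = 7
    out_dir: str = "plm_run"
    n_hvg: int = 200
    n_bins: int = 51
    synth: dict = field(default_factory=dict)  # SynthConfig overrides
    model: dict = field(default_factory=lambda: dict(
        n_layers=2, n_heads=4, d_model=64, d_ff=128, max_len=128, dropout=0.0))
    mlm: dict = field(default_factory=lambda: dict(epochs=4))
    annotate: dict = field(default_factory=lambda: dict(epochs=3))
    benchmark: dict = field(default_factory=lambda: dict(
        resolutions=[round(0.1 * i, 1) for i in range(1, 16)], n_neighbors=15))
    grn: dict = field(default_factory=lambda: dict(n_hubs=2, k=5, depth=2))
    programs: dict = field(default_factory=lambda: dict(
        resolution=1.0, n_neighbors=15))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir")  # output location is not part of the scientific config
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages in order; returns the manifest (also written to
    out_dir/manifest.json). Any stage failure raises with the stage name."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    cfg_hash = cfg.content_hash()
    with open(os.path.join(cfg.out_dir, "config.yaml"), "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh)
    artifacts: dict[str, str] = {}
    report: dict = {"config_hash": cfg_hash}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrap

    # -- synthesize ------------------------------------------------------
    def _synth():
        base = calibration_config(seed=cfg.seed)
        if cfg.synth:
            import dataclasses as _dc
            base = _dc.replace(base, **cfg.synth)
        corpus = generate_corpus(base)
        return split(corpus, (0.9, 0.1), stratify_by="batch", seed=cfg.seed)
    train_c, test_c = stage("synth")(_synth)

    # -- preprocess ------------------------------------------------------
    def _prep(c):
        m = normalize_log(c.matrix)
        m = select_hvgs(m, min(cfg.n_hvg, m.n_genes))
        return bin_expression(m, BinConfig(n_bins=cfg.n_bins))
    train_b = stage("preprocess")(lambda: _prep(train_c))
    hvg_genes = train_b.gene_ids
    # held-out split uses the training HVG set so vocabularies coincide
    test_b = stage("preprocess")(
        lambda: bin_expression(normalize_log(test_c.matrix).subset_genes(hvg_genes),
                               BinConfig(n_bins=cfg.n_bins)))
    vocab = build_vocabulary(hvg_genes)
    vocab_path = os.path.join(cfg.out_dir, "vocab.json")
    vocab.save_json(vocab_path)
    artifacts["vocab"] = vocab_path

    # -- stage 1: masked-value pretraining -------------------------------
    def _mlm():
        mc = ModelConfig(n_gene_tokens=vocab.n_tokens, n_value_bins=cfg.n_bins,
                         **cfg.model)
        tc = TrainConfig(stage="mlm", seed=cfg.seed, **cfg.mlm)
        return pretrain_mlm(train_b, vocab, tc, model_config=mc)
    state1, rep1 = stage("pretrain-mlm")(_mlm)
    report["mlm"] = {"epoch_losses": rep1.epoch_losses,
                     **evaluate_masked_mse(state1, test_b, vocab, seed=cfg.seed)}
    ckpt1 = os.path.join(cfg.out_dir, "stage1.npz")
    save_checkpoint(state1, ckpt1)
    artifacts["stage1_checkpoint"] = ckpt1

    # -- stage 2: annotation pretraining ---------------------------------
    def _annot():
        tc = TrainConfig(stage="annotate", seed=cfg.seed, **cfg.annotate)
        return pretrain_annotation(train_b, vocab, tc, init=state1)
    state2, rep2 = stage("pretrain-annot")(_annot)
    report["annotate"] = {"epoch_losses": rep2.epoch_losses, **rep2.metrics}
    ckpt2 = os.path.join(cfg.out_dir, "stage2.npz")
    save_checkpoint(state2, ckpt2)
    artifacts["stage2_checkpoint"] = ckpt2

    # -- zero-shot annotation of the held-out batch ----------------------
    def _zero_shot():
        labels = ann.zero_shot_annotate(state2, test_b, vocab)
        cm = ann.confusion(labels)
        labels_path = os.path.join(cfg.out_dir, "labels.tsv")
        labels.to_frame(test_b.cell_ids).to_csv(labels_path, sep="\t", index=False)
        cm_path = os.path.join(cfg.out_dir, "confusion.tsv")
        cm.to_tsv(cm_path)
        artifacts["labels"] = labels_path
        artifacts["confusion"] = cm_path
        return cm.accuracy()
    report["zero_shot_accuracy"] = stage("annotate")(_zero_shot)

    # -- integration benchmark -------------------------------------------
    def _bench():
        emb = ann.extract_embeddings(state2, test_b, vocab)
        return ann.benchmark(emb, test_b.cell_type, seed=cfg.seed,
                             **cfg.benchmark)
    bench = stage("benchmark")(_bench)
    report["benchmark"] = bench.to_dict()

    # -- attention network for the first held-out cell -------------------
    def _grn():
        sentences = encode_corpus(test_b, vocab, max_len=state2.config.max_len)
        att = grn_mod.cell_attention_matrix(state2, sentences[0], cfg.n_bins,
                                            vocab=vocab)
        hubs = grn_mod.select_hubs(att, cfg.grn["n_hubs"])
        net = grn_mod.expand_network(att, hubs, k=cfg.grn["k"],
                                     depth=cfg.grn["depth"])
        net_path = os.path.join(cfg.out_dir, "network.tsv")
        grn_mod.export_network(net, net_path, fmt="edge_tsv")
        artifacts["network"] = net_path
        return {"hubs": hubs, "n_nodes": len(net.nodes), "n_edges": len(net.edges)}
    report["grn"] = stage("grn")(_grn)

    # -- gene programs ----------------------------------------------------
    def _programs():
        table = prog_mod.extract_gene_embeddings(state2, vocab)
        assign = prog_mod.cluster_programs(table, seed=cfg.seed,
                                           **cfg.programs)
        m = select_hvgs(normalize_log(train_c.matrix), len(hvg_genes))
        activity = prog_mod.program_activity(assign, m)
        p_path = os.path.join(cfg.out_dir, "programs.tsv")
        assign.to_frame().to_csv(p_path, sep="\t", index=False)
        a_path = os.path.join(cfg.out_dir, "program_activity.tsv")
        activity.values.to_csv(a_path, sep="\t")
        artifacts["programs"] = p_path
        artifacts["program_activity"] = a_path
        return {"n_programs": assign.n_programs}
    report["programs"] = stage("programs")(_programs)

    report_path = os.path.join(cfg.out_dir, "report.json")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    artifacts["report"] = report_path
    manifest = {"config_hash": cfg_hash,
                "artifacts": {k: {"path": v, "sha256": _sha256(v)}
                              for k, v in artifacts.items()}}
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
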