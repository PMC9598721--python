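"""End-to-end workflow: generate -> extract -> train -> evolve -> retrieve
-> score, with every artifact stamped by the config hash and seed."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from avnlbp.config import RunConfig, stage_seed
from avnlbp.defam import DEParams, evolve, train_diverse_population
from avnlbp.descriptors import LBPHistogram
from avnlbp.retrieval import ImageDatabase, evaluate_retrieval
from avnlbp.synthetic import SyntheticSpec, generate, split_dataset

__all__ = ["run_pipeline", "PipelineArtifacts", "config_hash"]

logger = logging.getLogger(__name__)


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PipelineArtifacts:
    """Paths of the five artifact files a run emits."""

    histograms: Path
    networks: Path
    trace: Path
    metrics: Path
    config_snapshot: Path


def run_pipeline(config: RunConfig, outdir, images=None, labels=None) -> PipelineArtifacts:
    """Run the full retrieval workflow.

    With ``images``/``labels`` omitted, a synthetic database is generated
    from the config's synthetic keys.  Stages: stratified split, descriptor
    extraction, training of a diverse FAM population, differential
    evolution on the validation split, retrieval scoring of the test
    queries against the training-split index.  Any stage failure aborts
    with the stage name attached.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config_hash(config), "seed": config.seed}

    def stage(name):
        logger.info("stage %s (config %s)", name, stamp["config_hash"])
        return name

    current = stage("generate")
    try:
        if images is None:
            spec = SyntheticSpec(
                n_classes=config.n_classes,
                images_per_class=config.images_per_class,
                image_size=config.image_size,
                family=config.family,
                snr_db=config.snr_db,
                seed=stage_seed(config.seed, "generate"),
            )
            images, labels = generate(spec)
        labels = np.asarray(labels)

        current = stage("split")
        split = split_dataset(labels, config.split_fractions,
                              seed=stage_seed(config.seed, "split"))

        current = stage("extract")
        extractor = LBPHistogram(p=config.p, radius=config.radius,
                                 variant=config.variant,
                                 threshold=config.lbp_threshold,
                                 normalize=None).fit(None)
        hists = extractor.transform(images)
        norm = hists / np.maximum(hists.max(axis=1, keepdims=True), 1.0)
        hist_path = outdir / "histograms.csv"
        frame = pd.DataFrame(hists, columns=[f"h{k}" for k in range(hists.shape[1])])
        frame.insert(0, "label", labels)
        frame.insert(0, "id", np.arange(len(labels)))
        frame.to_csv(hist_path, index=False)

        current = stage("train")
        rng = np.random.default_rng(stage_seed(config.seed, "train"))
        population = train_diverse_population(
            norm[split.train], labels[split.train], config.n_networks, rng,
            rho=config.rho, alpha=config.alpha, beta=config.beta,
            epsilon=config.epsilon, epochs=config.epochs)

        current = stage("evolve")
        n_classes = len(np.unique(labels))
        params = DEParams(
            F1=config.F1, F2=config.F2, CR=config.CR,
            generations=config.generations, neigh_frac=config.neigh_frac,
            catmin=config.catmin if config.catmin is not None else n_classes,
            catmax=config.catmax, seed=stage_seed(config.seed, "evolve"))
        result = evolve(population, norm[split.validation],
                        labels[split.validation], params)
        trace_path = outdir / "trace.csv"
        pd.DataFrame(
            [{"generation": g, "best_value": r.value, "best_pcc": r.pcc,
              "best_na": r.n_active} for g, r in enumerate(result.trace)]
        ).to_csv(trace_path, index=False)
        net_path = outdir / "network.json"
        payload = result.network.to_json()
        payload["provenance"] = stamp
        with open(net_path, "w") as fh:
            json.dump(payload, fh)

        current = stage("retrieve")
        db = ImageDatabase(list(split.train), labels[split.train],
                           hists[split.train])
        metrics = evaluate_retrieval(
            db, norm[split.test], labels[split.test],
            classifier=result.network, metric=config.distance,
            arp_depth=config.arp_depth, arr_min_depth=config.arr_min_depth)
        metrics_path = outdir / "metrics.csv"
        summary = metrics.per_query.copy()
        summary["arp"] = metrics.arp
        summary["arr"] = metrics.arr
        summary["config_hash"] = stamp["config_hash"]
        summary["seed"] = stamp["seed"]
        summary.to_csv(metrics_path, index=False)

        snapshot_path = outdir / "config.json"
        with open(snapshot_path, "w") as fh:
            json.dump({**config.to_dict(), **stamp}, fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{current}' failed: {exc}") from exc

    return PipelineArtifacts(hist_path, net_path, trace_path, metrics_path,
                             snapshot_path)
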