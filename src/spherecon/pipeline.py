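"""End-to-end orchestration of the six-step pipeline.

filter -> dense connectome -> optimal-N selection -> N x N build -> global
metrics -> pairwise alignment -> reference selection -> sum network ->
(optional) group statistics.  All intermediates are written to the output
directory and recorded in a JSON manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io
from .alignment import pairwise_align_group, select_reference, sum_network
from .builder import build_dense_connectome, filter_by_length
from .io import RunConfig, ValidationError
from .metrics import connected_components, find_optimal_N, global_metrics, network_at_n

log = logging.getLogger("spherecon")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, subject: str | None, cause: Exception):
        self.stage = stage
        self.subject = subject
        where = f"stage {stage!r}" + (f", subject {subject!r}" if subject else "")
        super().__init__(f"pipeline failed at {where}: {cause}")


@dataclass
class PipelineManifest:
    subjects: list = field(default_factory=list)     # per-subject file dicts
    chosen_N: int | None = None
    reference_subject: int | None = None
    random_seed: int | None = None
    version: str = ""
    created: str = ""
    outputs: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)

    @classmethod
    def from_json(cls, path) -> "PipelineManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _stage(name, subject=None):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                log.info("stage %s%s done in %.2fs", name,
                         f" [{subject}]" if subject else "", dt)
                return False
            raise PipelineError(name, subject, exc) from exc
    return _Ctx()


def run_pipeline(config: RunConfig, subject_files: list, out_dir,
                 compute_metrics: bool = True) -> PipelineManifest:
    """Run the full pipeline on a cohort.

    ``subject_files`` is a list of dicts with keys ``surface`` and
    ``streamlines`` (paths).  Writes per-subject network CSVs, the sum
    network, a metrics JSON, and a manifest; returns the manifest.
    """
    if len(subject_files) < 2:
        raise ValidationError("the pipeline needs a cohort of >= 2 subjects "
                              "(alignment is pair-wise)")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__
    manifest = PipelineManifest(random_seed=config.random_seed,
                                version=__version__,
                                created=time.strftime("%Y-%m-%dT%H:%M:%S"))

    surfaces, denses = [], []
    for s_idx, files in enumerate(subject_files):
        name = f"subject{s_idx}"
        with _stage("read", name):
            surface = io.read_surface(files["surface"])
            lines = io.read_streamlines(files["streamlines"])
        with _stage("length-filter", name):
            kept, report = filter_by_length(
                lines, config.min_streamline_length_mm)
            log.info("%s: kept %d/%d streamlines (>= %g mm)", name,
                     report.n_kept, report.n_input, report.threshold_mm)
        with _stage("dense-connectome", name):
            dense = build_dense_connectome(kept, surface,
                                           config.endpoint_radius_mm)
        surfaces.append(surface)
        denses.append(dense)
        manifest.subjects.append({"id": name, **{k: str(v) for k, v
                                                 in files.items()}})

    with _stage("optimal-N"):
        chosen = find_optimal_N(denses, surfaces, config.node_counts_to_try)
        if chosen is None:
            raise ValidationError(
                "no candidate N keeps every subject fully connected")
        manifest.chosen_N = int(chosen)
        log.info("optimal N = %d", chosen)

    nets = []
    for s_idx, (dense, surface) in enumerate(zip(denses, surfaces)):
        with _stage("build-NxN", f"subject{s_idx}"):
            net = network_at_n(dense, surface, chosen)
            nets.append(net)
            path = out / f"subject{s_idx}_net.csv"
            io.write_adjacency(net, path)
            manifest.subjects[s_idx]["network"] = str(path)
            log.info("subject%d: nnz=%d components=%d", s_idx, net.nnz,
                     connected_components(net).n_components)

    if compute_metrics:
        with _stage("metrics"):
            all_metrics = {}
            for s_idx, net in enumerate(nets):
                gm = global_metrics(net, n_random=config.n_random_networks,
                                    rewires_per_edge=config.rewires_per_edge,
                                    seed=config.random_seed + s_idx)
                all_metrics[f"subject{s_idx}"] = {
                    k: getattr(gm, k)
                    for k in ("C", "L", "Q", "C_rand", "L_rand",
                              "Cr", "Lr", "swi")}
            path = out / "metrics.json"
            with open(path, "w") as fh:
                json.dump(all_metrics, fh, indent=2)
            manifest.outputs["metrics"] = str(path)

    with _stage("align"):
        group = pairwise_align_group(
            nets, restarts=config.sa_restarts,
            iterations=config.sa_iterations, seed=config.random_seed,
            cooling=config.cooling_factor)
        np.savetxt(out / "r_matrix.csv", group.r_matrix, fmt="%.6f",
                   delimiter=",")
        manifest.outputs["r_matrix"] = str(out / "r_matrix.csv")

    with _stage("reference"):
        ref = select_reference(group)
        manifest.reference_subject = int(ref)
        log.info("reference subject = %d", ref)

    with _stage("sum-network"):
        summed = sum_network(group)
        path = out / "sum_network.csv"
        np.savetxt(path, summed.counts, fmt="%d", delimiter=",")
        manifest.outputs["sum_network"] = str(path)

    manifest.to_json(out / "manifest.json")
    return manifest
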