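"""End-to-end study pipeline: preprocess -> classify -> cluster -> integrate
-> networks -> summaries, with a manifest of every emitted file."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from .config import StudyConfig
from .cluster import cluster_classified
from .dataio import (
    OmicsMatrix,
    summarize_counts,
    write_classification,
    write_counts_json,
    write_drop_log,
    write_matrix,
)
from .integrate import cluster_combined, join_omics_classes
from .network import build_network
from .preprocess import preprocess_matrix, preprocess_paired
from .simulate import SimDesign, simulate_study
from .spectral import ClassifiedSet, classify_dataset

log = logging.getLogger("tempomics")

HOURLY_FRAMES = ("TFH1", "TFH2")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineRun:
    """Outcome of one pipeline invocation."""

    config: StudyConfig
    out_dir: Path
    manifest: dict[str, str] = field(default_factory=dict)  # path -> sha256
    timings: dict[str, float] = field(default_factory=dict)
    classified: dict[tuple[str, str], ClassifiedSet] = field(default_factory=dict)

    def register(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.manifest[str(path.relative_to(self.out_dir))] = digest

    def write_manifest(self) -> None:
        payload = {
            "config_sha256": hashlib.sha256(
                json.dumps(self.config.to_dict(), sort_keys=True).encode()
            ).hexdigest(),
            "seed": self.config.seed,
            "timings_s": {k: round(v, 3) for k, v in self.timings.items()},
            "files": self.manifest,
        }
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(payload, indent=2))


def _kind_for(omic: str, config: StudyConfig) -> str:
    return "intensity" if omic in config.boxcox_omics else "counts"


def run_pipeline(
    config: StudyConfig,
    out_dir: str | Path,
    matrices: dict[tuple[str, str], OmicsMatrix] | None = None,
    simulate: SimDesign | None = None,
) -> PipelineRun:
    """Run the whole study. Provide input ``matrices`` keyed by
    (omic, frame) or a :class:`SimDesign` to generate them. Idempotent given
    the same config and seed."""
    if (matrices is None) == (simulate is None):
        raise PipelineError("provide exactly one of matrices / simulate")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    run = PipelineRun(config=config, out_dir=out_dir)
    t0 = time.perf_counter()

    if simulate is not None:
        matrices, truth = simulate_study(simulate)
        sim_dir = out_dir / "simulated"
        sim_dir.mkdir(exist_ok=True)
        for (omic, frame), m in matrices.items():
            p = sim_dir / f"{omic}_{frame}.tsv"
            write_matrix(m, p)
            run.register(p)
        truth_path = sim_dir / "ground_truth.tsv"
        truth.to_csv(truth_path, sep="\t", index=False)
        run.register(truth_path)
        run.timings["simulate"] = time.perf_counter() - t0
    assert matrices is not None

    omics = sorted({omic for omic, _ in matrices})
    drops = []
    classified: dict[tuple[str, str], ClassifiedSet] = {}
    for omic in omics:
        kind = _kind_for(omic, config)
        frames = {frame: m for (o, frame), m in matrices.items() if o == omic}
        sets = {}
        for frame, m in frames.items():
            t = time.perf_counter()
            ts, d = preprocess_matrix(m, config, kind=kind)
            drops += [(f"{omic}:{a}", f"{frame}/{stage}", why) for a, stage, why in d]
            sets[frame] = ts
            run.timings[f"preprocess/{omic}/{frame}"] = time.perf_counter() - t
        if all(f in frames for f in HOURLY_FRAMES):
            t = time.perf_counter()
            ts, d = preprocess_paired(frames["TFH2"], frames["TFH1"], config, kind=kind)
            drops += [(f"{omic}:{a}", f"TFdelta/{stage}", why) for a, stage, why in d]
            sets["TFdelta"] = ts
            run.timings[f"preprocess/{omic}/TFdelta"] = time.perf_counter() - t
        for frame, ts in sets.items():
            t = time.perf_counter()
            try:
                cs = classify_dataset(ts, config)
                cluster_classified(cs, config.cluster)
            except Exception as exc:  # pragma: no cover - context wrapper
                raise PipelineError(f"classify failed for {omic}/{frame}: {exc}") from exc
            classified[(omic, frame)] = cs
            p = out_dir / f"classified_{omic}_{frame}.tsv"
            write_classification(cs, p)
            run.register(p)
            if cs.cutoffs is not None:
                p = out_dir / f"cutoffs_{omic}_{frame}.json"
                cs.cutoffs.to_json(p)
                run.register(p)
            run.timings[f"classify/{omic}/{frame}"] = time.perf_counter() - t
            log.info("classified %s/%s: %d series", omic, frame, len(cs.records))
    run.classified = classified

    drop_path = out_dir / "drop_log.tsv"
    write_drop_log(drops, drop_path)
    run.register(drop_path)

    counts = summarize_counts([cs for cs in classified.values()])
    counts_path = out_dir / "class_counts.json"
    write_counts_json(counts, counts_path)
    run.register(counts_path)

    # cross-omics integration per frame
    t = time.perf_counter()
    frames_present = sorted({frame for _, frame in classified})
    for frame in frames_present:
        per_omic = [classified[(o, f)] for (o, f) in sorted(classified) if f == frame]
        if len(per_omic) < 2:
            continue
        combined = join_omics_classes(per_omic)
        merged, _ = cluster_combined(combined, config.cluster)
        p = out_dir / f"combined_{frame}.tsv"
        write_classification(merged, p)
        run.register(p)
    run.timings["integrate"] = time.perf_counter() - t

    # networks for the configured frames
    t = time.perf_counter()
    net_dir = out_dir / "networks"
    net_dir.mkdir(exist_ok=True)
    for frame in config.network.frames:
        per_omic = [classified[(o, f)] for (o, f) in sorted(classified) if f == frame]
        if not per_omic:
            continue
        for cc in join_omics_classes(per_omic):
            if len(cc.members) < 2:
                continue
            net = build_network(cc.members, frame, cc.class_label)
            safe = cc.class_label.replace(" ", "")
            p = net_dir / f"network_{frame}_{safe}.json"
            net.to_json(p)
            run.register(p)
    run.timings["networks"] = time.perf_counter() - t

    run.timings["total"] = time.perf_counter() - t0
    run.write_manifest()
    return run
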