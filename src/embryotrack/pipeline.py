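"""End-to-end orchestration: filter → detect → (optional segment) → track →
score, with a run manifest that records every parameter and seed so any
output can be reproduced byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .detect import DogParams, FblsParams, dog_detect, extract_local_maxima, fbls_smooth
from .gmcf import GmcfParams, gmcf_filter
from .io import read_lineage, read_timelapse, write_lineage, write_mask
from .metrics import GoldStandard, score_forest
from .model import CentreSet, Channel, LineageForest, TimeLapseDataset
from .subsurf import SubSurfParams, cell_density, segment_embryo
from .track import AnnealConfig, track

__all__ = ["PipelineConfig", "run_pipeline", "run_from_manifest"]


@dataclass
class PipelineConfig:
    """Configuration of a full reconstruction run.

    Exactly one detector (``"fbls"`` or ``"dog"``) is active.  ``seed``
    feeds every stochastic stage; there are no implicit seeds.
    """

    out_dir: str = "run"
    input_patterns: dict | None = None    # channel -> TIFF pattern with {t}
    spacing: tuple[float, float, float] = (1.37, 1.37, 1.37)
    dt_seconds: float = 67.0
    detector: str = "fbls"
    run_filter: bool = True
    segment_embryo_volume: bool = False
    gold_path: str | None = None
    r_factor: float = 0.5
    seed: int = 0
    gmcf: GmcfParams = field(default_factory=lambda: GmcfParams(K=0.01))
    fbls: FblsParams = field(default_factory=FblsParams)
    dog: DogParams = field(default_factory=DogParams)
    subsurf: SubSurfParams = field(default_factory=SubSurfParams)
    anneal: AnnealConfig = field(default_factory=lambda: AnnealConfig(d_max=6.0, n_sweeps=40))

    def __post_init__(self):
        if self.detector not in ("fbls", "dog"):
            raise ValueError("detector must be 'fbls' or 'dog'")

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        return d

    @classmethod
    def from_manifest(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d.pop("version", None)
        for key, klass in [("gmcf", GmcfParams), ("fbls", FblsParams),
                           ("dog", DogParams), ("subsurf", SubSurfParams),
                           ("anneal", AnnealConfig)]:
            if isinstance(d.get(key), dict):
                d[key] = klass(**d[key])
        if d.get("spacing") is not None:
            d["spacing"] = tuple(d["spacing"])
        return cls(**d)


def _detect_frame(config: PipelineConfig, grid) -> CentreSet:
    if config.run_filter:
        grid = gmcf_filter(grid, config.gmcf)
    if config.detector == "fbls":
        smoothed = fbls_smooth(grid, config.fbls)
        return extract_local_maxima(smoothed, config.fbls.intensity_floor)
    return dog_detect(grid, config.dog)


def _json_default(o):
    if dataclasses.is_dataclass(o) and not isinstance(o, type):
        return dataclasses.asdict(o)
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {o!r}")


def run_pipeline(config: PipelineConfig,
                 dataset: TimeLapseDataset | None = None) -> dict:
    """Run the reconstruction workflow and write all artifacts to ``out_dir``.

    Returns a dict with the lineage forest, per-frame centre sets, the score
    report (when a gold standard was supplied) and the artifact paths.  Any
    stage failure is re-raised annotated with the stage and frame index.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if dataset is None:
        if not config.input_patterns:
            raise ValueError("either a dataset or input_patterns is required")
        dataset = read_timelapse(config.input_patterns, config.spacing,
                                 config.dt_seconds)

    centre_sets: list[CentreSet] = []
    nuclei = dataset.channel_series(Channel.NUCLEI)
    for t, grid in enumerate(nuclei):
        try:
            cs = _detect_frame(config, grid)
        except Exception as e:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(f"stage 'detect' failed at frame {t}: {e}") from e
        centre_sets.append(cs)
        frame_forest = LineageForest(cs.centres)
        write_lineage(frame_forest, out / f"centres_t{t:04d}.csv")

    try:
        cfg_track = dataclasses.replace(config.anneal, seed=config.seed)
        forest = track(centre_sets, cfg_track)
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"stage 'track' failed: {e}") from e
    write_lineage(forest, out / "lineage.csv")

    result: dict = {
        "forest": forest,
        "centre_sets": centre_sets,
        "paths": {"lineage": str(out / "lineage.csv")},
    }

    if config.segment_embryo_volume:
        try:
            mask = segment_embryo(nuclei[0], config.subsurf)
        except Exception as e:  # noqa: BLE001
            raise RuntimeError(f"stage 'segment' failed at frame 0: {e}") from e
        write_mask(mask.mask, out / "embryo_mask_t0000.tif")
        count, density = cell_density(centre_sets[0], mask)
        result["embryo"] = {
            "volume_um3": mask.volume_um3,
            "cell_count": count,
            "density_per_um3": density,
        }

    if config.gold_path:
        gold = GoldStandard(forest=read_lineage(config.gold_path))
        report = score_forest(forest, gold, r_factor=config.r_factor)
        report = {k: v for k, v in report.items() if k != "matching"}
        result["score"] = report
        with open(out / "score.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default, sort_keys=True)
        result["paths"]["score"] = str(out / "score.json")

    manifest = config.to_manifest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default, sort_keys=True)
    result["paths"]["manifest"] = str(out / "manifest.json")
    return result


def run_from_manifest(manifest_path, out_dir: str | None = None) -> dict:
    """Re-run a pipeline from a recorded manifest (byte-identical outputs)."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    config = PipelineConfig.from_manifest(manifest)
    if out_dir is not None:
        config.out_dir = out_dir
    return run_pipeline(config)
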