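"""End-to-end prioritization run: label -> weights -> criteria -> rank.

A run is described by a :class:`RunConfig` (YAML or JSON on disk).  Stages:

1. label the catalog against the mention index and summarize the gaps;
2. aggregate expert pairwise matrices, derive weights, screen consistency
   (a consistency ratio >= 0.1 aborts the run unless explicitly allowed);
3. select the prioritizable subset for the requested objective;
4. assemble the criteria matrix — from a criteria CSV when supplied,
   otherwise synthesized from the run seed (with the hospitalization
   criterion computed from claims records, packaged or supplied);
5. normalize in distributive mode, score and rank.

All outputs (ranking.csv, gap_report.json, weights.json, consistency.json,
run.log) are computed in memory first and written together at the end, so
a failing stage leaves no partial artifacts.  Outputs carry provenance
headers without timestamps: identical configs give identical bytes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from . import ahp, catalog as cat, io as pio, mcda, synth

__all__ = [
    "PipelineError",
    "InconsistentJudgmentsError",
    "RunConfig",
    "run_pipeline",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class InconsistentJudgmentsError(PipelineError):
    """Expert judgments failed the consistency screen (CR >= threshold)."""

    def __init__(self, cr: float, threshold: float):
        self.cr = cr
        self.threshold = threshold
        super().__init__(
            "weights",
            f"consistency ratio {cr:.4f} >= {threshold}; judgments rejected "
            "(pass allow_inconsistent=True to override)",
        )


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one prioritization run."""

    objective: int = 3
    out_dir: Union[str, Path] = "prioritycompass_run"
    seed: int = 0
    catalog: Optional[Union[str, Path]] = None  # default: packaged WHO menu
    mentions: Optional[Union[str, Path]] = None  # default: packaged fixture
    matrices: tuple[str, ...] = ()  # expert pairwise CSVs; default: synthetic
    claims: Optional[Union[str, Path]] = None  # claims CSV; default: synthetic
    criteria: Optional[Union[str, Path]] = None  # criteria CSV; default: synthetic
    exclusions: Optional[Union[str, Path]] = None  # default: packaged list
    method: str = "eigenvector"
    tiebreak: tuple[str, ...] = mcda.DEFAULT_TIEBREAK
    allow_inconsistent: bool = False

    def __post_init__(self) -> None:
        if self.objective not in (3, 4):
            raise ValueError("objective must be 3 or 4")

    @classmethod
    def from_file(cls, path: Union[str, Path], **overrides) -> "RunConfig":
        """Load YAML or JSON; keyword overrides win (e.g. ``seed=...``)."""
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {unknown}")
        raw.update(overrides)
        for key in ("matrices", "tiebreak"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["out_dir"] = str(out["out_dir"])
        for key in ("catalog", "mentions", "claims", "criteria", "exclusions"):
            if out[key] is not None:
                out[key] = str(out[key])
        out["matrices"] = [str(p) for p in out["matrices"]]
        out["tiebreak"] = list(out["tiebreak"])
        return out

    def hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = self.to_dict()
        payload.pop("out_dir")
        return pio.config_hash(payload)


def _load_catalog(config: RunConfig) -> cat.InterventionCatalog:
    if config.catalog is None:
        return cat.who_reference_catalog()
    frame = pio.read_table(config.catalog, required=["code"])
    return cat.build_catalog(frame)


def _load_mentions(config: RunConfig) -> pd.DataFrame:
    if config.mentions is None:
        return cat.iran_mention_fixture()
    return pio.read_table(
        config.mentions, required=["code", "document_id", "document_class"]
    )


def _load_exclusions(config: RunConfig) -> Optional[frozenset[str]]:
    if config.exclusions is None:
        return None  # packaged default
    frame = pio.read_table(config.exclusions, required=["code"])
    return frozenset(frame["code"].str.strip())


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute all stages; returns a name -> path map of written outputs."""
    log: list[str] = []
    synth_cfg = synth.SynthConfig(seed=config.seed)
    cfg_hash = config.hash()

    # -- stage: catalog + labelling ----------------------------------------
    try:
        catalog = _load_catalog(config)
        labels = cat.label_interventions(catalog, _load_mentions(config))
        report = cat.gap_report(labels, catalog)
    except Exception as exc:
        raise PipelineError("label", str(exc)) from exc
    log.append(
        "label: "
        + " ".join(f"{k}={report.by_label.get(k, 0)}" for k in cat.LABELS)
    )

    # -- stage: weights ----------------------------------------------------
    try:
        if config.matrices:
            mats = [pio.read_pairwise_csv(p) for p in config.matrices]
        else:
            mats = synth.gen_expert_matrices(synth_cfg)
            log.append(
                f"weights: no matrices supplied, generated "
                f"{len(mats)} synthetic expert matrices (seed={config.seed})"
            )
        group = ahp.aggregate_expert_matrices(mats)
        w_arr, _ = ahp.derive_weights(group, method=config.method)
        weights = pd.Series(w_arr, index=list(group.labels), name="weight")
        consistency = ahp.consistency_ratio(group)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("weights", str(exc)) from exc
    log.append(f"weights: CR={consistency.cr:.6f} passed={consistency.passed}")
    if not consistency.passed and not config.allow_inconsistent:
        raise InconsistentJudgmentsError(consistency.cr, consistency.threshold)

    # -- stage: prioritizable subset ---------------------------------------
    try:
        subset = cat.filter_prioritizable(
            catalog, _load_exclusions(config), objective=config.objective
        )
    except Exception as exc:
        raise PipelineError("filter", str(exc)) from exc
    log.append(f"filter: objective {config.objective} -> {len(subset)} items")

    # -- stage: criteria assembly ------------------------------------------
    try:
        if config.criteria is not None:
            frame = pio.read_frame_csv(config.criteria, dtype={"code": str})
            frame = frame.set_index("code")
            missing = [c for c in subset.codes if c not in frame.index]
            if missing:
                raise ValueError(f"criteria CSV lacks rows for {missing[:5]}")
            matrix = frame.loc[list(subset.codes), list(weights.index)].astype(float)
            log.append("criteria: loaded from file (claims stage skipped)")
        else:
            claims_records = (
                pio.read_table(
                    config.claims,
                    required=["icd10_code", "admissions"],
                    numeric=["admissions"],
                )
                if config.claims is not None
                else None
            )
            matrix = synth.gen_criteria_matrix(
                synth_cfg, subset, claims_records=claims_records
            )
            source = "file" if config.claims is not None else "synthetic"
            log.append(f"criteria: synthesized (claims source: {source})")
    except Exception as exc:
        raise PipelineError("criteria", str(exc)) from exc

    # -- stage: rank -------------------------------------------------------
    try:
        ranking = mcda.build_ranking(matrix, weights, tiebreak=config.tiebreak)
    except Exception as exc:
        raise PipelineError("rank", str(exc)) from exc
    log.append(f"rank: {len(ranking)} interventions ranked")

    # -- write everything at once ------------------------------------------
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ranking": out_dir / "ranking.csv",
        "gap_report": out_dir / "gap_report.json",
        "weights": out_dir / "weights.json",
        "consistency": out_dir / "consistency.json",
        "log": out_dir / "run.log",
    }
    pio.write_frame_csv(ranking, paths["ranking"], seed=config.seed,
                        cfg_hash=cfg_hash)
    pio.write_json(report.to_dict(), paths["gap_report"], seed=config.seed,
                   cfg_hash=cfg_hash)
    pio.write_weights_json(weights, consistency, paths["weights"],
                           seed=config.seed, cfg_hash=cfg_hash)
    pio.write_json(consistency.to_dict(), paths["consistency"],
                   seed=config.seed, cfg_hash=cfg_hash)
    paths["log"].write_text("\n".join(log) + "\n", encoding="utf-8")
    return paths
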