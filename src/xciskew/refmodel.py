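"""The three-tier reference model of allelic expression on X.

From a reference cohort's CVAC tables three nested beta-binomial nulls are
fitted:

* a *position model* per site covered by >= ``min_reads`` RNA reads in
  >= ``min_samples`` samples, fitted on those samples' count pairs;
* a *gene model* per gene, pooling all (position, sample) pairs within the
  gene under the same depth/sample eligibility applied to the pooled
  observations;
* one *global model*, fitted on pairs pooled from a fixed-size random
  sample of distinct positions (without replacement, seeded).

Reference counts are Laplace-smoothed before fitting; patient counts are
never smoothed. The model serializes to versioned JSON and the
deserialized model reproduces downstream p-values bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .betabinom import BetaBinParams, EligibilityError, fit_betabinom
from .sites import NO_GENE

__all__ = [
    "ReferenceModel",
    "ModelFileError",
    "position_key",
    "eligible_position_keys",
    "build_position_models",
    "build_gene_models",
    "build_global_model",
    "build_reference_model",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

FORMAT_NAME = "xciskew-reference-model"
FORMAT_VERSION = 1


class ModelFileError(RuntimeError):
    """Corrupt, truncated or version-incompatible model file."""


def position_key(chrom: str, pos: int) -> str:
    return f"{chrom}:{pos}"


@dataclasses.dataclass
class ReferenceModel:
    position_models: dict[str, BetaBinParams]
    gene_models: dict[str, BetaBinParams]
    global_model: BetaBinParams
    metadata: dict

    def n_models(self) -> tuple[int, int]:
        return len(self.position_models), len(self.gene_models)


def _depth_ok(df: pd.DataFrame, min_reads: int) -> pd.Series:
    return (df["ref_count"] + df["alt_count"]) >= min_reads


def eligible_position_keys(
    cohort: pd.DataFrame, min_reads: int = 3, min_samples: int = 10
) -> set[str]:
    """Positions covered by >= min_reads RNA reads in >= min_samples
    samples (the position-model eligibility rule)."""
    ok = cohort[_depth_ok(cohort, min_reads)]
    counts = ok.groupby(["chrom", "pos"])["sample_id"].nunique()
    return {
        position_key(chrom, pos)
        for (chrom, pos), n in counts.items()
        if n >= min_samples
    }


def build_position_models(
    cohort: pd.DataFrame,
    min_reads: int = 3,
    min_samples: int = 10,
    k_smooth: float = 1.0,
) -> dict[str, BetaBinParams]:
    """Fit one beta-binomial per eligible position on the qualifying
    samples' (ref, alt) pairs."""
    if cohort.empty:
        raise ValueError("empty reference cohort")
    models: dict[str, BetaBinParams] = {}
    ok = cohort[_depth_ok(cohort, min_reads)]
    for (chrom, pos), grp in ok.groupby(["chrom", "pos"], sort=True):
        if grp["sample_id"].nunique() < min_samples:
            continue
        key = position_key(chrom, pos)
        pairs = list(zip(grp["ref_count"], grp["alt_count"]))
        try:
            models[key] = fit_betabinom(
                pairs, k_smooth=k_smooth, min_pairs=min_samples,
                tier="position", key=key,
            )
        except EligibilityError:  # pragma: no cover - guarded above
            continue
    logger.info("fitted %d position models", len(models))
    return models


def build_gene_models(
    cohort: pd.DataFrame,
    min_reads: int = 3,
    min_samples: int = 10,
    k_smooth: float = 1.0,
) -> dict[str, BetaBinParams]:
    """Fit one beta-binomial per gene by pooling eligible (position,
    sample) observations across the gene."""
    if cohort.empty:
        raise ValueError("empty reference cohort")
    models: dict[str, BetaBinParams] = {}
    annotated = cohort[cohort["gene"] != NO_GENE]
    ok = annotated[_depth_ok(annotated, min_reads)]
    for gene, grp in ok.groupby("gene", sort=True):
        pairs = list(zip(grp["ref_count"], grp["alt_count"]))
        if len(pairs) < min_samples:
            continue
        models[str(gene)] = fit_betabinom(
            pairs, k_smooth=k_smooth, min_pairs=min_samples,
            tier="gene", key=str(gene),
        )
    logger.info("fitted %d gene models", len(models))
    return models


def build_global_model(
    cohort: pd.DataFrame,
    n_positions: int = 2000,
    seed: int = 7,
    min_reads: int = 3,
    k_smooth: float = 1.0,
) -> BetaBinParams:
    """Fit the chromosome-wide fallback model on pairs pooled from
    ``n_positions`` distinct positions sampled without replacement."""
    if cohort.empty:
        raise ValueError("empty reference cohort")
    ok = cohort[_depth_ok(cohort, min_reads)]
    positions = sorted({(c, int(p)) for c, p in zip(ok["chrom"], ok["pos"])})
    rng = np.random.default_rng(seed)
    if len(positions) <= n_positions:
        if len(positions) < n_positions:
            logger.warning(
                "cohort has only %d distinct positions (< %d requested); "
                "using all of them",
                len(positions),
                n_positions,
            )
        chosen = positions
    else:
        idx = rng.choice(len(positions), size=n_positions, replace=False)
        chosen = [positions[i] for i in sorted(idx)]
    chosen_set = set(chosen)
    mask = [
        (c, int(p)) in chosen_set for c, p in zip(ok["chrom"], ok["pos"])
    ]
    sub = ok[np.asarray(mask)]
    pairs = list(zip(sub["ref_count"], sub["alt_count"]))
    return fit_betabinom(
        pairs, k_smooth=k_smooth, min_pairs=1, tier="global", key="global"
    )


def build_reference_model(
    cohort: pd.DataFrame,
    min_reads: int = 3,
    min_samples: int = 10,
    global_n: int = 2000,
    seed: int = 7,
    k_smooth: float = 1.0,
) -> ReferenceModel:
    """Fit all three tiers and bundle them with reproducibility metadata."""
    pos_models = build_position_models(cohort, min_reads, min_samples, k_smooth)
    gene_models = build_gene_models(cohort, min_reads, min_samples, k_smooth)
    global_model = build_global_model(cohort, global_n, seed, min_reads, k_smooth)
    metadata = {
        "cohort_size": int(cohort["sample_id"].nunique()),
        "min_reads": int(min_reads),
        "min_samples": int(min_samples),
        "global_n_positions": int(global_n),
        "seed": int(seed),
        "k_smooth": float(k_smooth),
        "parameterization": "GAMLSS-BB (alpha=mu/sigma, beta=(1-mu)/sigma)",
    }
    return ReferenceModel(pos_models, gene_models, global_model, metadata)


def _params_to_dict(p: BetaBinParams) -> dict:
    return {
        "mu": p.mu,
        "sigma": p.sigma,
        "n_observations": p.n_observations,
        "tier": p.tier,
        "key": p.key,
        "loglik": p.loglik,
        "converged": p.converged,
    }


def _params_from_dict(d: Mapping) -> BetaBinParams:
    try:
        return BetaBinParams(
            mu=float(d["mu"]),
            sigma=float(d["sigma"]),
            n_observations=int(d["n_observations"]),
            tier=d["tier"],
            key=str(d["key"]),
            loglik=float(d.get("loglik", float("nan"))),
            converged=bool(d.get("converged", True)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFileError(f"malformed model parameters: {exc}") from exc


def save_model(model: ReferenceModel, path: str | Path) -> None:
    """Serialize to versioned JSON (floats at full round-trip precision)."""
    doc = {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "metadata": model.metadata,
        "position_models": {
            k: _params_to_dict(v) for k, v in sorted(model.position_models.items())
        },
        "gene_models": {
            k: _params_to_dict(v) for k, v in sorted(model.gene_models.items())
        },
        "global_model": _params_to_dict(model.global_model),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_model(path: str | Path) -> ReferenceModel:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelFileError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != FORMAT_NAME:
        raise ModelFileError(f"{path} is not a {FORMAT_NAME} file")
    if doc.get("version") != FORMAT_VERSION:
        raise ModelFileError(
            f"{path}: unsupported model version {doc.get('version')!r}"
        )
    try:
        return ReferenceModel(
            position_models={
                k: _params_from_dict(v) for k, v in doc["position_models"].items()
            },
            gene_models={
                k: _params_from_dict(v) for k, v in doc["gene_models"].items()
            },
            global_model=_params_from_dict(doc["global_model"]),
            metadata=dict(doc["metadata"]),
        )
    except KeyError as exc:
        raise ModelFileError(f"{path}: missing section {exc}") from exc
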