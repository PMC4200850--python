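"""Synthetic multi-output bioactivity endpoint tables with known ground truth.

The generator emulates the statistical structure of a large curated
bioactivity extract — thousands of compound x condition records spread
sparsely over many measures, assays, organisms and targets, with strongly
condition-dependent activity priors — without emulating real chemistry
space. Three design elements matter:

* **Molecules** are assembled from drug-like ring and chain fragments over
  C/N/O/S, so the entropy descriptor theta_5 varies across compounds.
* **Condition subsets are chemically stratified**: every condition value
  (each assay, target, organism, measure) carries a descriptor "center"
  and preferentially samples compounds near it, the way real assays probe
  particular chemical series. This is precisely the heterogeneity the
  moving-average model feeds on — without it all condition averages
  coincide and the deviation features collapse into one another.
* **Labels come from a planted affine model on the MA features** through a
  Bernoulli link. Because the MA statistics themselves depend on the
  labels, label probabilities are solved as a damped fixed point of the
  expected-label map (probabilities -> active-set statistics -> scores ->
  probabilities) and the final labels are a single Bernoulli draw from the
  converged probabilities. Statistics recomputed from the drawn labels
  then converge to the generating statistics as condition subsets grow,
  which is what makes refitting the discriminant a consistent recovery of
  the planted direction.

Each condition value's center is an increasing function of its configured
activity prior: under the planted coefficients and the default link, the
net descriptor effect on the activity probability is positive, so
high-descriptor chemistry is the more active chemistry. Configured priors
therefore steer the empirical per-condition
activity rates (they correlate strongly at realistic subset sizes) but are
not reproduced exactly — the labels are fully determined by the planted
feature model, not by the priors.

Defaults mirror the modeled extract's shape: 3548 records over 3091
compounds, 37 measures, 493 assays, 11 organisms and 169 targets, with
per-condition activity priors drawn uniformly from [0.2, 0.95].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .descriptors import MarkovShannonEncoder, build_graph
from .errors import DataError
from .features import AlmaFeaturizer
from .records import CONDITION_COLUMNS, CURATION_QUALITY, ENDPOINT_COLUMNS

__all__ = ["SynthConfig", "generate_molecules", "generate_endpoints", "simulate"]

# Published reference coefficients double as the default planted truth.
_DEFAULT_COEF = (-0.403994, 0.199322, 0.434889, -0.020189, -0.001660)
_DEFAULT_INTERCEPT = 1.139556

_RINGS = (
    "c1ccccc1", "c1ccncc1", "c1ccoc1", "c1ccsc1", "c1cc[nH]c1",
    "C1CCCCC1", "C1CCNCC1", "C1CCOCC1", "C1CCCC1", "C1CNCCN1",
    "c1ccc2ccccc2c1", "c1ccc2[nH]ccc2c1",
)
_CHAIN_ATOMS = "CCCNOS"
_CAPS = ("C", "N", "O", "C(=O)O", "C(=O)N", "C#N", "Cl", "F", "C#C")

_CURATION_PROBS = (0.5, 0.3, 0.2)  # expert / intermediate / autocuration


@dataclass
class SynthConfig:
    """Generator settings; a fixed seed makes the output byte-identical.

    Parameters
    ----------
    n_compounds, n_records, n_measures, n_assays, n_organisms, n_targets
        Dataset shape. Defaults follow the modeled extract.
    intercept, coef
        The planted affine model on the five MA features; defaults are the
        shipped reference coefficients.
    prior_range : (float, float)
        Range the per-condition activity priors are drawn from; priors
        steer each condition's chemistry (and hence its activity rate)
        through the stratified assignment.
    stratification : float
        Width, in bits of theta_5, of the Gaussian preference kernel that
        draws compounds toward a condition's descriptor center. Smaller is
        purer chemistry per condition; 0 disables identifiable structure,
        very small widths make the condition averages deterministic
        functions of the centers and re-collinearize the deviations.
    link : {"logistic", "step"}
        Label law given the planted score: Bernoulli through a logistic,
        or a noise-free threshold at the midpoint.
    link_scale : float
        Sharpness of the logistic link; 6.0 gives label determinism
        comparable to a strongly separating discriminant.
    link_midpoint : float
        Score at which the link crosses probability 0.5. The default 1.3
        centers the label law inside the planted score distribution so the
        overall activity rate lands near 40% — between a balanced design
        and the modeled extract's minority-active class balance — instead
        of the saturated >80% a zero midpoint would produce.
    """

    n_compounds: int = 3091
    n_records: int = 3548
    n_measures: int = 37
    n_assays: int = 493
    n_organisms: int = 11
    n_targets: int = 169
    intercept: float = _DEFAULT_INTERCEPT
    coef: tuple[float, ...] = _DEFAULT_COEF
    prior_range: tuple[float, float] = (0.2, 0.95)
    stratification: float = 0.6
    link: str = "logistic"
    link_scale: float = 6.0
    link_midpoint: float = 1.3
    seed: int = 0
    max_retries: int = 5

    def __post_init__(self) -> None:
        for name in ("n_compounds", "n_records", "n_measures", "n_assays",
                     "n_organisms", "n_targets"):
            if getattr(self, name) < 1:
                raise DataError(f"{name} must be >= 1")
        lo, hi = self.prior_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise DataError("prior_range must satisfy 0 <= lo <= hi <= 1")
        if len(self.coef) != 5:
            raise DataError("planted model needs exactly five coefficients")
        if self.link not in ("logistic", "step"):
            raise DataError("link must be 'logistic' or 'step'")
        if self.stratification <= 0:
            raise DataError("stratification width must be positive")


def _random_smiles(rng: np.random.Generator) -> str:
    """One drug-like SMILES: 1-2 ring systems joined by a short chain."""
    parts = [str(rng.choice(_RINGS))]
    if rng.random() < 0.7:
        chain = "".join(
            rng.choice(list(_CHAIN_ATOMS))
            for _ in range(rng.integers(1, 5))
        )
        parts.append(chain)
        if rng.random() < 0.6:
            parts.append(str(rng.choice(_RINGS)))
        else:
            parts.append(str(rng.choice(_CAPS)))
    return "".join(parts)


def generate_molecules(config: SynthConfig) -> list[tuple[str, str]]:
    """Deterministic list of (compound id, SMILES) pairs.

    Every SMILES is validated by round-tripping through the descriptor
    builder; invalid draws are redrawn, so all outputs parse and yield
    finite descriptors.
    """
    rng = np.random.default_rng(config.seed)
    out: list[tuple[str, str]] = []
    for i in range(config.n_compounds):
        for _ in range(50):
            smi = _random_smiles(rng)
            try:
                build_graph(smi, str(i))
            except Exception:  # noqa: BLE001 - redraw invalid chemistry
                continue
            break
        else:  # pragma: no cover - the fragment grammar is valid by design
            raise DataError("could not generate a valid SMILES in 50 draws")
        out.append((f"CPD{i:05d}", smi))
    return out


def _condition_vocab(config: SynthConfig) -> dict[str, list[str]]:
    return {
        "measure": [f"Measure-{i:02d} (nM)" for i in range(config.n_measures)],
        "assay_id": [f"{700000 + i}" for i in range(config.n_assays)],
        "organism": [f"organism_{i:02d}" for i in range(config.n_organisms)],
        "target_id": [f"T{i:04d}" for i in range(config.n_targets)],
    }


def _soft_features(frame: pd.DataFrame, probs: np.ndarray) -> np.ndarray:
    """MA feature matrix under expected labels (activity probabilities).

    The hard-label statistics p1 = n1/n and mean theta over actives are
    replaced by their expectations: p1 = mean prob and a prob-weighted
    theta mean. This is the population version of the featurizer's
    statistics and its fixed point is what sampled-label statistics
    estimate.
    """
    out = np.empty((len(frame), 5))
    quality = frame["curation_level"].map(CURATION_QUALITY).to_numpy(dtype=float)
    theta = frame["theta5"].to_numpy(dtype=float)
    out[:, 0] = quality * theta
    work = pd.DataFrame({"p": probs, "pth": probs * theta})
    for j, cls in enumerate(CONDITION_COLUMNS, start=1):
        grouped = work.groupby(frame[cls].to_numpy())
        p1 = grouped["p"].mean()
        mean_theta = (grouped["pth"].sum() / grouped["p"].sum()).fillna(0.0)
        ma = (p1 * mean_theta).to_dict()
        out[:, j] = theta - frame[cls].map(ma).to_numpy(dtype=float)
    return out


def _link_probability(scores: np.ndarray, config: SynthConfig) -> np.ndarray:
    z = config.link_scale * (np.asarray(scores, dtype=float) - config.link_midpoint)
    if config.link == "step":
        return (z > 0).astype(float)
    return 1.0 / (1.0 + np.exp(-z))


def generate_endpoints(
    config: SynthConfig,
    molecules: Optional[list[tuple[str, str]]] = None,
) -> tuple[pd.DataFrame, dict]:
    """Endpoint table plus ground truth for the planted model.

    Returns ``(frame, truth)`` where ``frame`` follows the endpoint CSV
    schema and ``truth`` records the planted intercept/coefficients, the
    per-condition configured priors and descriptor centers, and each row's
    converged planted score and activity probability.
    """
    if molecules is None:
        molecules = generate_molecules(config)
    if not molecules:
        raise DataError("generate_endpoints requires at least one molecule")

    encoder = MarkovShannonEncoder(k_max=5)
    theta5 = encoder.fit_transform([smi for _, smi in molecules])[:, 5]
    smiles_of = dict(molecules)
    vocab = _condition_vocab(config)
    coef = np.asarray(config.coef, dtype=float)
    lo_p, hi_p = config.prior_range
    th_lo, th_hi = float(theta5.min()), float(theta5.max())

    def center_of(prior: float) -> float:
        # increasing map: high-prior conditions get high-descriptor chemistry
        if hi_p == lo_p:
            frac = 0.5
        else:
            frac = (prior - lo_p) / (hi_p - lo_p)
        return th_lo + frac * (th_hi - th_lo)

    for attempt in range(config.max_retries):
        rng = np.random.default_rng((config.seed, attempt))
        priors = {
            cls: dict(zip(values, rng.uniform(lo_p, hi_p, size=len(values))))
            for cls, values in vocab.items()
        }
        idx = rng.integers(0, len(molecules), size=config.n_records)
        theta_rec = theta5[idx]
        cids = [molecules[i][0] for i in idx]
        frame = pd.DataFrame(
            {
                "compound_id": cids,
                "smiles": [smiles_of[c] for c in cids],
                "curation_level": rng.choice(
                    list(CURATION_QUALITY), size=config.n_records,
                    p=_CURATION_PROBS,
                ),
            }
        )
        w = config.stratification
        for cls, values in vocab.items():
            centers = np.array([center_of(priors[cls][v]) for v in values])
            logits = -((theta_rec[:, None] - centers[None, :]) ** 2) / (2 * w * w)
            pref = np.exp(logits - logits.max(axis=1, keepdims=True))
            pref /= pref.sum(axis=1, keepdims=True)
            u = rng.random(config.n_records)
            choice = (pref.cumsum(axis=1) < u[:, None]).sum(axis=1)
            frame[cls] = [values[j] for j in choice]
        frame["theta5"] = theta_rec

        # damped expected-label fixed point: probs -> MA stats -> scores -> probs
        probs = np.full(config.n_records, 0.5)
        for _ in range(80):
            feats = _soft_features(frame, probs)
            new = _link_probability(config.intercept + feats @ coef, config)
            if np.abs(new - probs).mean() < 1e-7:
                probs = new
                break
            probs = 0.5 * probs + 0.5 * new
        # the recorded scores and label probabilities come from the final
        # statistics, so a step link yields exactly separable labels
        scores = config.intercept + _soft_features(frame, probs) @ coef
        probs = _link_probability(scores, config)

        labels = (rng.random(config.n_records) < probs).astype(int)
        if 0 < labels.sum() < config.n_records:
            break
        warnings.warn(
            "degenerate one-class label draw; regenerating with a fresh "
            "substream",
            stacklevel=2,
        )
    else:
        raise DataError(
            "label generation stayed degenerate after "
            f"{config.max_retries} attempts; widen prior_range"
        )

    frame["label"] = labels
    truth = {
        "intercept": config.intercept,
        "coef": [float(c) for c in coef],
        "link": config.link,
        "link_scale": config.link_scale,
        "stratification": config.stratification,
        "seed": config.seed,
        "priors": {cls: {k: float(v) for k, v in m.items()}
                   for cls, m in priors.items()},
        "centers": {cls: {k: float(center_of(v)) for k, v in m.items()}
                    for cls, m in priors.items()},
        "scores": [float(s) for s in scores],
        "probabilities": [float(p) for p in probs],
    }
    out = frame[list(ENDPOINT_COLUMNS)].copy()
    out["label"] = out["label"].astype("Int64")
    return out, truth


def simulate(config: SynthConfig) -> tuple[pd.DataFrame, dict]:
    """Molecules + endpoints in one call (the CLI's `simulate` backend)."""
    molecules = generate_molecules(config)
    return generate_endpoints(config, molecules)


def refit_features(frame: pd.DataFrame, theta_column: str = "theta5"):
    """Convenience: featurizer fitted on a labeled table plus its matrix."""
    featurizer = AlmaFeaturizer(theta_column=theta_column).fit(frame)
    return featurizer, featurizer.transform(frame)
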