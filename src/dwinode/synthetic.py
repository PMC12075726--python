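"""Synthetic cohorts and image phantoms.

The study this package supports compared nine diffusion parameters
between benign and metastatic retropharyngeal lymph nodes, but the
patient data are private.  This module generates (a) node-level cohort
tables whose per-group parameter distributions, node counts and
size/morphology frequencies match the published summaries, and (b) 4-D
multi-b-value image phantoms with known per-node generating parameters
and Rician measurement noise, so that the fitting and statistics stages
can be exercised and validated end to end.

Cohort sampling is at the node level (the study analyzed 68 nodes from
59 patients and likewise ignored within-patient clustering).  The nine
parameters are sampled independently by default — the source tables
give no covariance — from normals truncated to physical bounds; the
bounds sit far in the tails, so truncation shifts moments by well under
0.5%.  An optional single-latent-factor correlation and a skew-normal
option for individual parameters are available for sensitivity studies;
neither claims fidelity to the original data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .fitting import PARAMETER_NAMES
from .models import BValueProtocol, forward_signal, MonoExpParams

__all__ = [
    "PARAM_BOUNDS",
    "MIAD_EDGES_MM",
    "GroupSpec",
    "default_group_specs",
    "sample_cohort",
    "NodePlacement",
    "PhantomSpec",
    "generate_phantom",
    "rician",
]

#: Physical truncation bounds per diffusion parameter.
PARAM_BOUNDS = {
    "adc": (1e-4, 5.0),
    "ddc_sem": (1e-4, 5.0),
    "d_froc": (1e-4, 5.0),
    "d_ctrw": (1e-4, 5.0),
    "alpha_sem": (0.01, 1.0),
    "beta_froc": (0.01, 1.0),
    "alpha_ctrw": (0.01, 1.0),
    "beta_ctrw": (0.01, 1.0),
    "mu_froc": (0.1, 50.0),
}

#: Minimal-axial-diameter category edges, mm ([6,8), [8,10), [10,20]).
MIAD_EDGES_MM = (6.0, 8.0, 10.0, 20.0)
MIAD_CATEGORIES = ("6-8", "8-10", ">=10")
MAAD_CATEGORIES = ("6-10", "10-20", ">=20")

#: +1 where higher values are metastatic-like, -1 where benign-like
#: (used to orient the optional shared latent severity factor).
_METASTATIC_DIRECTION = {
    "adc": -1, "ddc_sem": -1, "d_froc": -1, "d_ctrw": -1, "alpha_ctrw": -1,
    "alpha_sem": +1, "beta_froc": +1, "mu_froc": +1, "beta_ctrw": +1,
}


@dataclass(frozen=True)
class GroupSpec:
    """Generating distribution of one diagnostic group.

    ``params`` maps each of the nine parameter names to ``(mean, sd)``;
    ``miad_probs``/``maad_probs`` are the three size-category
    probabilities; ``correlation`` (rho in [0, 1)) couples the nine
    parameters through one latent severity factor; ``skew`` optionally
    maps parameter names to a skew-normal shape (moment-matched to the
    same mean/SD).
    """

    label: str
    n: int
    params: dict
    miad_probs: tuple
    maad_probs: tuple
    homogeneous_prob: float
    well_defined_prob: float
    male_prob: float
    age_mean: float
    age_sd: float
    correlation: float = 0.0
    skew: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("group size must be positive")
        if set(self.params) != set(PARAMETER_NAMES):
            raise ValueError("params must cover exactly the nine diffusion parameters")
        for name, (mean, sd) in self.params.items():
            if sd <= 0:
                raise ValueError(f"SD for {name!r} must be positive")
        for probs in (self.miad_probs, self.maad_probs):
            if len(probs) != 3 or abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ValueError("category probabilities must be length 3 and sum to 1")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError("correlation must be in [0, 1)")


def default_group_specs(**overrides) -> tuple:
    """The packaged benign/metastatic generating specs.

    Keyword overrides (e.g. ``correlation=0.5`` or ``n_benign=100``)
    apply to both or either group.
    """
    with resources.files("dwinode.data").joinpath("cohort_defaults.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    specs = []
    for key in ("benign", "metastatic"):
        g = raw[key]
        spec = GroupSpec(
            label=g["label"],
            n=overrides.get(f"n_{key}", g["n"]),
            params={k: (v["mean"], v["sd"]) for k, v in g["params"].items()},
            miad_probs=tuple(c / sum(g["miad_counts"]) for c in g["miad_counts"]),
            maad_probs=tuple(c / sum(g["maad_counts"]) for c in g["maad_counts"]),
            homogeneous_prob=g["homogeneous_count"] / g["n"],
            well_defined_prob=g["well_defined_count"] / g["n"],
            male_prob=g["male_count"] / g["n"],
            age_mean=g["age"]["mean"],
            age_sd=g["age"]["sd"],
            correlation=overrides.get("correlation", 0.0),
            skew=overrides.get("skew", {}),
        )
        specs.append(spec)
    return tuple(specs)


def _truncnorm(mean, sd, lo, hi, size, rng):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _skewnorm_matched(mean, sd, shape, size, rng, lo, hi):
    # Moment-match loc/scale so the skew-normal keeps the target mean/SD.
    delta = shape / np.sqrt(1.0 + shape**2)
    scale = sd / np.sqrt(1.0 - 2.0 * delta**2 / np.pi)
    loc = mean - scale * delta * np.sqrt(2.0 / np.pi)
    x = sps.skewnorm.rvs(shape, loc=loc, scale=scale, size=size, random_state=rng)
    return np.clip(x, lo, hi)


def _sample_group(spec: GroupSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n
    cols = {}
    if spec.correlation > 0.0:
        # One shared latent severity factor, oriented so metastatic-like
        # deviations co-occur; marginals stay N(mean, sd) up to clipping.
        rho = spec.correlation
        f = rng.standard_normal(n)
        for name in PARAMETER_NAMES:
            mean, sd = spec.params[name]
            e = rng.standard_normal(n)
            z = np.sqrt(rho) * _METASTATIC_DIRECTION[name] * f + np.sqrt(1.0 - rho) * e
            cols[name] = np.clip(mean + sd * z, *PARAM_BOUNDS[name])
    else:
        for name in PARAMETER_NAMES:
            mean, sd = spec.params[name]
            lo, hi = PARAM_BOUNDS[name]
            if name in spec.skew:
                cols[name] = _skewnorm_matched(mean, sd, spec.skew[name], n, rng, lo, hi)
            else:
                cols[name] = _truncnorm(mean, sd, lo, hi, n, rng)

    cat_idx = rng.choice(3, size=n, p=spec.miad_probs)
    lo_edges = np.asarray(MIAD_EDGES_MM[:-1])[cat_idx]
    hi_edges = np.asarray(MIAD_EDGES_MM[1:])[cat_idx]
    cols["miad_mm"] = rng.uniform(lo_edges, hi_edges)
    cols["miad_category"] = np.asarray(MIAD_CATEGORIES)[cat_idx]
    cols["maad_category"] = np.asarray(MAAD_CATEGORIES)[rng.choice(3, size=n, p=spec.maad_probs)]
    cols["homogeneous"] = rng.random(n) < spec.homogeneous_prob
    cols["well_defined"] = rng.random(n) < spec.well_defined_prob
    cols["sex"] = np.where(rng.random(n) < spec.male_prob, "M", "F")
    cols["age"] = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 18.0, 95.0)
    df = pd.DataFrame(cols)
    df.insert(0, "group", spec.label)
    return df


def sample_cohort(benign: GroupSpec, metastatic: GroupSpec, seed: int) -> pd.DataFrame:
    """Draw a two-group node-level cohort table, reproducibly.

    Columns: node_id, group, the nine diffusion parameters, MiAD in mm
    and by category, maximum-axial-diameter category, T2 signal
    homogeneity, border definition, sex and age.
    """
    rng = np.random.default_rng(seed)
    df = pd.concat([_sample_group(benign, rng), _sample_group(metastatic, rng)], ignore_index=True)
    df.insert(0, "node_id", [f"node{i:04d}" for i in range(len(df))])
    return df


# ---------------------------------------------------------------------------
# Image phantoms


@dataclass(frozen=True)
class NodePlacement:
    """One elliptical node on the phantom grid.

    ``center``/``radii`` are in-plane voxel coordinates on slice
    ``z``; the signal follows ``model`` with ``params``.  An optional
    concentric necrotic core (fraction of each radius) decays with
    free-water-like Gaussian diffusion and is reported as an exclusion
    mask, mimicking regions an observer would exclude from an ROI.
    """

    center: tuple
    radii: tuple
    z: int
    model: str
    params: object
    necrotic_core_frac: float = 0.0

    def __post_init__(self):
        if min(self.radii) <= 0:
            raise ValueError("node radii must be positive")
        if not 0.0 <= self.necrotic_core_frac < 1.0:
            raise ValueError("necrotic core fraction must be in [0, 1)")


@dataclass(frozen=True)
class PhantomSpec:
    """Grid, protocol, node placements and noise level of a phantom."""

    shape: tuple = (32, 32, 1)
    protocol: BValueProtocol = BValueProtocol()
    nodes: tuple = ()
    snr: float = np.inf
    seed: int = 0

    def __post_init__(self):
        if len(self.shape) != 3 or min(self.shape) < 1:
            raise ValueError("phantom grid must be 3-D")
        if not self.snr > 0:
            raise ValueError("SNR must be positive (np.inf for noiseless)")


_NECROTIC_ADC = 2.5  # um^2/ms, free-water-like core


def _ellipse_mask(shape, center, radii, z):
    xx, yy = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    inplane = ((xx - center[0]) / radii[0]) ** 2 + ((yy - center[1]) / radii[1]) ** 2 <= 1.0
    m = np.zeros(shape, dtype=bool)
    if not 0 <= z < shape[2]:
        raise ValueError("node slice outside grid")
    m[:, :, z] = inplane
    return m


def rician(signal: np.ndarray, snr: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude-MRI noise: |signal + complex Gaussian| with sigma = 1/SNR
    relative to a unit b=0 signal."""
    if np.isinf(snr):
        return np.asarray(signal, dtype=float).copy()
    sigma = 1.0 / snr
    e1 = rng.standard_normal(signal.shape)
    e2 = rng.standard_normal(signal.shape)
    return np.sqrt((signal + sigma * e1) ** 2 + (sigma * e2) ** 2)


def generate_phantom(spec: PhantomSpec) -> dict:
    """Render a 4-D multi-b-value phantom with known truth.

    Returns a dict with the noisy ``image`` (x, y, z, b), per-node
    boolean ``masks`` and ``exclusions`` (necrotic cores), the
    ``truth`` table of generating parameters, and the noiseless image.
    Nodes may not overlap (the truth would become ambiguous).
    """
    shape = spec.shape
    b = spec.protocol.b
    noiseless = np.zeros(shape + (b.size,))
    occupied = np.zeros(shape, dtype=bool)
    masks, exclusions, truth = {}, {}, []

    for i, node in enumerate(spec.nodes):
        m = _ellipse_mask(shape, node.center, node.radii, node.z)
        if not np.any(m):
            raise ValueError(f"node {i} covers no voxels")
        if np.any(m & occupied):
            raise ValueError(f"node {i} overlaps a previously placed node")
        occupied |= m
        core = np.zeros(shape, dtype=bool)
        if node.necrotic_core_frac > 0:
            core = _ellipse_mask(
                shape, node.center, tuple(r * node.necrotic_core_frac for r in node.radii), node.z
            )
        decay = forward_signal(node.model, b, node.params, spec.protocol)
        noiseless[m] = decay
        if np.any(core):
            noiseless[core] = forward_signal("monoexp", b, MonoExpParams(_NECROTIC_ADC))
        node_id = f"node{i}"
        masks[node_id] = m
        exclusions[node_id] = core
        truth.append(
            {
                "node_id": node_id,
                "model": node.model,
                "params": {k: float(v) for k, v in vars(node.params).items()},
                "voxels": int(np.count_nonzero(m & ~core)),
            }
        )

    rng = np.random.default_rng(spec.seed)
    image = rician(noiseless, spec.snr, rng)
    return {
        "image": image,
        "noiseless": noiseless,
        "masks": masks,
        "exclusions": exclusions,
        "truth": truth,
        "protocol": spec.protocol,
    }
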