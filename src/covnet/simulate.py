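"""Synthetic morphometric cohorts with controllable covariance structure.

The generator draws subject-level regional values from a multivariate
normal whose latent correlation matrix follows a three-factor structure
mirroring what group-level morphometric covariance looks like in practice:

* a **global factor** shared by every region (overall brain/head size),
  contributing a pervasive baseline correlation ``r_global`` to all pairs;
* one **module factor** per block of regions, contributing ``r_in`` extra
  correlation within each block (segregation);
* a **graded integration factor** with per-region hub weights,
  contributing on average ``r_out`` extra correlation between blocks
  (integration).  Hub weights vary linearly within each block over
  ``1 ± hub_spread``, so some regions are strongly integrative hubs whose
  cross-block correlations rival weak within-block pairs — as in real
  cortical covariance, where inter-lobe correlations of hub regions
  overlap intra-lobe ones.

The single *group effect* multiplier scales the integration factor of
group B (the module loadings are re-balanced so within-block correlations
are preserved to within a few percent): a multiplier below 1
weakens precisely the cross-module
covariance, i.e. fragments network integration while leaving segregation
intact.  Because hub-carried cross-block pairs then drop below within-block
pairs in the correlation *ranking*, the effect survives matched-density
binarization — a uniform two-level block model would not, since scaling a
homogeneous between-block pool barely changes which edges pass a
fixed-edge-count threshold.

Linear age and sex effects and i.i.d. measurement noise are added on top,
then values are shifted/scaled to region-specific profiles
(surface-area-like: hundreds to thousands of mm²; thickness-like:
1.5-4.5 mm).  Implied correlation matrices are validated to be positive
semi-definite before sampling.  Everything is deterministic given the spec
seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import SURFACE_AREA, THICKNESS, MorphometricCohort, write_cohort
from .regions import RegionSet, default_regions


@dataclass
class SyntheticSpec:
    """Ground-truth parameters of a synthetic two-group cohort."""

    n_per_group: tuple[int, int] = (50, 49)
    n_blocks: int = 6
    r_global: float = 0.25   # baseline correlation from the shared size factor
    r_in: float = 0.35       # extra within-block (module) correlation
    r_out: float = 0.15      # mean extra between-block (integration) correlation
    hub_spread: float = 0.6  # relative spread of per-region integration weights
    group_effect: float = 1.0  # multiplier on group B's integration factor
    metric: str = SURFACE_AREA
    age_range: tuple[float, float] = (45.0, 80.0)
    age_slope_frac: float = -0.002   # fractional change in region mean per year
    sex_offset_frac: float = 0.05    # male minus female, as fraction of mean
    scale_frac: float = 0.10         # structured latent SD as fraction of mean
    noise_sd_frac: float = 0.05      # i.i.d. noise SD as fraction of mean
    clinical: bool = True
    seed: int = 0
    regions: RegionSet = field(default_factory=default_regions)

    def block_assignment(self) -> np.ndarray:
        """Block index per region: contiguous, near-equal blocks in region order."""
        R = len(self.regions)
        if not 1 <= self.n_blocks <= R:
            raise ValidationError("n_blocks must be between 1 and the region count")
        return np.floor(np.arange(R) * self.n_blocks / R).astype(int)

    def hub_weights(self) -> np.ndarray:
        """Per-region integration weights, graded within each block, mean 1."""
        blocks = self.block_assignment()
        u = np.empty(blocks.size)
        for b in range(self.n_blocks):
            idx = np.flatnonzero(blocks == b)
            u[idx] = np.linspace(1 - self.hub_spread, 1 + self.hub_spread, idx.size)
        u = np.clip(u, 0.01, None)
        return u / u.mean()

    def correlation_for_group(self, which: str) -> np.ndarray:
        """Implied latent correlation matrix for group 'A' or 'B' (PSD-checked)."""
        mult = self.group_effect if which == "B" else 1.0
        if mult < 0:
            raise ValidationError("group_effect must be non-negative")
        blocks = self.block_assignment()
        g = np.sqrt(self.r_global)
        a = np.sqrt(mult * self.r_out * self.hub_weights())
        resid = self.r_in - a**2
        if (self.r_global + self.r_in > 1) or (resid < 0).any():
            raise ValidationError(
                "factor loadings exceed unit variance; reduce r_global/r_in/r_out "
                "or hub_spread"
            )
        c = np.sqrt(resid)
        C = np.full((blocks.size, blocks.size), g * g) + np.outer(a, a)
        same = blocks[:, None] == blocks[None, :]
        C[same] += np.outer(c, c)[same]
        np.fill_diagonal(C, 1.0)
        lo = float(np.linalg.eigvalsh(C)[0])
        if lo < -1e-10:
            raise ValidationError(
                f"implied correlation matrix is not PSD (min eigenvalue {lo:.3e})"
            )
        return C

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["regions"] = {"names": list(self.regions.names),
                        "hemispheres": list(self.regions.hemispheres)}
        return d

    @classmethod
    def from_manifest(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        reg = d.pop("regions")
        for key in ("n_per_group", "age_range"):
            d[key] = tuple(d[key])
        return cls(regions=RegionSet(tuple(reg["names"]), tuple(reg["hemispheres"])), **d)


def _region_profiles(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    R = len(spec.regions)
    if spec.metric == THICKNESS:
        return rng.uniform(1.5, 4.5, size=R)
    # surface-area-like: log-uniform means between 500 and 10000 mm²
    return np.exp(rng.uniform(np.log(500.0), np.log(10000.0), size=R))


def generate_cohort(spec: SyntheticSpec) -> MorphometricCohort:
    """Draw a two-group cohort ('A', 'B') from the spec's generative model."""
    rng = np.random.default_rng(spec.seed)
    R = len(spec.regions)
    means = _region_profiles(spec, rng)
    # per-region covariate effect sizes, fixed for the whole cohort
    age_slope = spec.age_slope_frac * means * rng.uniform(0.5, 1.5, size=R)
    sex_offset = spec.sex_offset_frac * means * rng.uniform(0.5, 1.5, size=R)

    chunks, metas = [], []
    age_mid = float(np.mean(spec.age_range))
    for which, n in zip(("A", "B"), spec.n_per_group):
        if n < 4:
            raise ValidationError("each synthetic group needs at least 4 subjects")
        C = spec.correlation_for_group(which)
        L = np.linalg.cholesky(C + 1e-12 * np.eye(R))
        Z = rng.standard_normal((n, R)) @ L.T
        age = rng.uniform(*spec.age_range, size=n)
        male = rng.integers(0, 2, size=n)
        eps = rng.standard_normal((n, R))
        values = means * (1.0 + spec.scale_frac * Z + spec.noise_sd_frac * eps)
        values += age_slope * (age - age_mid)[:, None]
        values += sex_offset * male[:, None]
        if (values <= 0).any():  # astronomically rare at default scales
            values = np.clip(values, 1e-6 * means, None)
        meta = pd.DataFrame({
            "group": which,
            "age": np.round(age, 2),
            "sex": np.where(male == 1, "M", "F"),
        })
        if spec.clinical:
            meta["updrs_iii"] = np.round(np.clip(rng.normal(54, 13, n), 5, 108), 1)
            meta["mmse"] = rng.integers(22, 31, size=n)
            meta["ledd"] = np.round(np.clip(rng.normal(818, 350, n), 0, None), 1)
            duration = np.round(np.clip(rng.normal(7.5, 3.0, n), 0.5, None), 1)
            meta["duration"] = duration
            meta["onset_age"] = np.round(age - duration, 1)
        metas.append(meta)
        chunks.append(values)

    n_total = sum(spec.n_per_group)
    subjects = [f"sub-{i + 1:03d}" for i in range(n_total)]
    values = pd.DataFrame(np.vstack(chunks), index=subjects,
                          columns=list(spec.regions.labels))
    meta = pd.concat(metas, ignore_index=True)
    meta.index = pd.Index(subjects)
    return MorphometricCohort(values=values, meta=meta, regions=spec.regions,
                              metric=spec.metric)


def write_fixture(cohort: MorphometricCohort, directory,
                  spec: SyntheticSpec | None = None) -> dict[str, Path]:
    """Write the TSV pair plus a ground-truth manifest; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "morphometrics": directory / "morphometrics.tsv",
        "metadata": directory / "metadata.tsv",
        "manifest": directory / "manifest.json",
    }
    write_cohort(cohort, paths["morphometrics"], paths["metadata"])
    manifest = {"metric": cohort.metric, "n_subjects": len(cohort.subjects),
                "group_sizes": cohort.group_sizes}
    if spec is not None:
        manifest["spec"] = spec.to_manifest()
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths
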