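"""Synthetic four-group label-free proteomics studies with known ground truth.

The generator draws protein-level log2 abundances from a log-normal model
(per-protein baseline, within-group noise), plants three kinds of signal —

* differential proteins whose DVD (case) group mean is shifted against all
  three control groups,
* group-specific proteins generated above the detection limit only in one
  group,
* diagnostic markers whose DVD shift is chosen to hit a target AUC under the
  equal-variance binormal model —

then partitions each protein's per-sample abundance across a fixed set of
peptides (Dirichlet-drawn ionization proportions) and applies left-censoring
at a detection threshold plus optional random dropout.  All randomness flows
from a single seed through deterministic substreams, so identical
configurations produce byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._errors import ConfigError
from .io_tables import GROUPS, replicate_column

#: Group sizes of the emulated study design (21 NC / 22 T2DM / 14 VD / 12 DVD).
DEFAULT_GROUP_SIZES = {"NC": 21, "T2DM": 22, "VD": 14, "DVD": 12}

CASE_GROUP = "DVD"

# log2-FC dead zone of the DEP thresholds; planted effects must clear it.
_DEAD_ZONE = max(np.log2(1.20), -np.log2(0.83))


def plant_marker_shift(target_auc: float, sd: float) -> float:
    """log2 mean shift giving ``target_auc`` under equal-variance normals.

    For case and control scores N(mu + delta, sd^2) and N(mu, sd^2) the AUC is
    Phi(delta / (sd * sqrt(2))), hence delta = sqrt(2) * sd * Phi^-1(AUC).
    """
    if not 0.5 < target_auc < 1.0:
        raise ConfigError(f"target AUC must lie in (0.5, 1), got {target_auc}")
    if sd <= 0:
        raise ConfigError("sd must be positive")
    return float(np.sqrt(2.0) * sd * norm.ppf(target_auc))


@dataclass
class SimulationConfig:
    group_sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_proteins: int = 1000
    peptides_per_protein: tuple[int, int] = (2, 8)
    baseline_log2_mean: float = 27.0
    baseline_log2_sd: float = 1.5
    within_group_log2_sd: float = 1.0
    replicate_log2_sd: float = 0.2
    dep_fraction: float = 0.05
    dep_log2fc_range: tuple[float, float] = (0.5, 3.0)
    group_specific_fraction: float = 0.02
    detection_log2_threshold: float = 20.0
    dropout_rate: float = 0.02
    marker_specs: Sequence[tuple[str, float]] = ()
    replicates: int = 2
    seed: int = 0

    def validate(self) -> None:
        if set(self.group_sizes) != set(GROUPS):
            raise ConfigError(f"group_sizes must cover exactly {GROUPS}")
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ConfigError(f"group {g} needs >= 2 samples, got {n}")
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be positive")
        lo, hi = self.peptides_per_protein
        if not (1 <= lo <= hi):
            raise ConfigError("peptides_per_protein range invalid")
        for name in ("baseline_log2_sd", "within_group_log2_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.replicate_log2_sd < 0:
            raise ConfigError("replicate_log2_sd must be >= 0")
        for name in ("dep_fraction", "group_specific_fraction", "dropout_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        flo, fhi = self.dep_log2fc_range
        if not flo <= fhi:
            raise ConfigError("dep_log2fc_range must be nondecreasing")
        if flo <= _DEAD_ZONE:
            raise ConfigError(
                "dep_log2fc_range must exclude the fold-change dead zone "
                f"(|log2FC| <= {_DEAD_ZONE:.4f}) so planted effects clear the thresholds"
            )
        for prot, auc in self.marker_specs:
            if not 0.5 <= auc < 1.0:
                raise ConfigError(f"marker target AUC {auc} outside [0.5, 1)")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")


@dataclass
class SimulationTruth:
    """Planted ground truth: protein -> effect, for recovery tests.

    ``dep_proteins`` maps accession to the true DVD-vs-each-control log2 fold
    change (the same shift is applied against all three control groups).
    Planted markers are also DVD-upregulated DEPs and appear in both maps.
    """

    dep_proteins: dict[str, float]
    specific_proteins: dict[str, str]
    marker_proteins: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p, lfc in sorted(self.dep_proteins.items()):
            rows.append({"protein": p, "kind": "dep", "value": lfc})
        for p, g in sorted(self.specific_proteins.items()):
            rows.append({"protein": p, "kind": "group_specific", "value": g})
        for p, auc in sorted(self.marker_proteins.items()):
            rows.append({"protein": p, "kind": "marker", "value": auc})
        return pd.DataFrame(rows, columns=["protein", "kind", "value"])


def protein_accession(i: int) -> str:
    """Accession of the i-th simulated protein (0-based)."""
    return f"SIM{i + 1:05d}"


def _sample_ids(group_sizes: Mapping[str, int]) -> tuple[list[str], list[str]]:
    samples, groups = [], []
    for g in GROUPS:
        for j in range(group_sizes[g]):
            samples.append(f"{g}{j + 1:02d}")
            groups.append(g)
    return samples, groups


def simulate_study(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Generate (peptide table, metadata, truth) for one synthetic study."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_assign, rng_effect, rng_abund, rng_pep, rng_drop = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    n = config.n_proteins
    proteins = [protein_accession(i) for i in range(n)]
    index_of = {p: i for i, p in enumerate(proteins)}

    # --- choose planted proteins ------------------------------------------
    marker_idx: dict[int, float] = {}
    for prot, auc in config.marker_specs:
        if prot not in index_of:
            raise ConfigError(f"marker protein {prot!r} not among the {n} simulated proteins")
        marker_idx[index_of[prot]] = float(auc)

    free = np.array([i for i in range(n) if i not in marker_idx])
    rng_assign.shuffle(free)
    n_dep = int(round(config.dep_fraction * n))
    n_spec = int(round(config.group_specific_fraction * n))
    if n_dep + n_spec > len(free):
        raise ConfigError("dep_fraction + group_specific_fraction plant more proteins than exist")
    dep_idx = free[:n_dep]
    spec_idx = free[n_dep:n_dep + n_spec]

    lfc = np.zeros(n)
    flo, fhi = config.dep_log2fc_range
    magnitudes = rng_effect.uniform(flo, fhi, size=len(dep_idx))
    signs = rng_effect.choice([-1.0, 1.0], size=len(dep_idx))
    lfc[dep_idx] = magnitudes * signs
    for i, auc in marker_idx.items():
        lfc[i] = plant_marker_shift(auc, config.within_group_log2_sd)

    spec_group = {int(i): GROUPS[rng_effect.integers(len(GROUPS))] for i in spec_idx}

    truth = SimulationTruth(
        dep_proteins={proteins[i]: float(lfc[i]) for i in np.concatenate([dep_idx, list(marker_idx)]).astype(int)} if n_dep + len(marker_idx) else {},
        specific_proteins={proteins[i]: g for i, g in spec_group.items()},
        marker_proteins={proteins[i]: auc for i, auc in marker_idx.items()},
    )

    # --- protein-level log2 abundance per sample --------------------------
    samples, groups_per_sample = _sample_ids(config.group_sizes)
    n_samp = len(samples)
    is_case = np.array([g == CASE_GROUP for g in groups_per_sample])

    baseline = rng_abund.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    log2_abund = (
        baseline[:, None]
        + rng_abund.normal(0.0, config.within_group_log2_sd, size=(n, n_samp))
        + lfc[:, None] * is_case[None, :]
    )
    group_arr = np.array(groups_per_sample)
    for i, g in spec_group.items():
        log2_abund[i, group_arr != g] = -np.inf  # absent outside its group

    # --- peptide decomposition --------------------------------------------
    lo, hi = config.peptides_per_protein
    n_pep = rng_pep.integers(lo, hi + 1, size=n)
    total_pep = int(n_pep.sum())
    prop = np.empty(total_pep)
    pos = 0
    for i in range(n):
        prop[pos:pos + n_pep[i]] = rng_pep.dirichlet(np.ones(n_pep[i]))
        pos += n_pep[i]

    pep_protein = np.repeat(np.arange(n), n_pep)
    pep_number = np.concatenate([np.arange(1, k + 1) for k in n_pep])

    reps = config.replicates
    # raw intensity: protein abundance x peptide proportion x replicate noise
    with np.errstate(invalid="ignore"):
        log2_pep = (
            log2_abund[pep_protein][:, :, None]
            + np.log2(prop)[:, None, None]
            + rng_pep.normal(0.0, config.replicate_log2_sd, size=(total_pep, n_samp, reps))
        )
    intensity = np.exp2(log2_pep)
    intensity[log2_pep < config.detection_log2_threshold] = 0.0
    if config.dropout_rate > 0:
        drop = rng_drop.random(size=intensity.shape) < config.dropout_rate
        intensity[drop] = 0.0

    # --- assemble long table ----------------------------------------------
    prot_col = np.repeat([proteins[i] for i in pep_protein], n_samp * reps)
    pep_col = np.repeat(
        [f"{proteins[i]}_pep{j}" for i, j in zip(pep_protein, pep_number)], n_samp * reps
    )
    sample_col = np.tile(np.repeat(samples, reps), total_pep)
    rep_col = np.tile(np.arange(1, reps + 1), total_pep * n_samp)
    table = pd.DataFrame(
        {
            "protein": prot_col,
            "peptide": pep_col,
            "sample": sample_col,
            "replicate": rep_col,
            "intensity": intensity.reshape(-1),
        }
    )

    metadata = pd.DataFrame(
        {
            "sample": np.repeat(samples, reps),
            "group": np.repeat(groups_per_sample, reps),
            "replicate": np.tile(np.arange(1, reps + 1), n_samp),
        }
    )
    return table, metadata, truth


# ---------------------------------------------------------------------------
# flat key=value config files (for the CLI)

_TUPLE_KEYS = {"peptides_per_protein", "dep_log2fc_range"}
_INT_KEYS = {"n_proteins", "replicates", "seed"}


def load_sim_config(path) -> SimulationConfig:
    """Parse a flat ``key=value`` file into a SimulationConfig.

    ``group_sizes`` is written ``NC:21,T2DM:22,VD:14,DVD:12``; ranges are
    comma-separated pairs; ``marker_specs`` is ``SIM00001:0.85,SIM00002:0.9``.
    Unknown keys raise.
    """
    kv: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"bad config line: {line!r}")
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()

    valid = {f for f in SimulationConfig.__dataclass_fields__}
    unknown = set(kv) - valid
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")

    kwargs: dict = {}
    for key, val in kv.items():
        if key == "group_sizes":
            kwargs[key] = {
                g.strip(): int(c) for g, c in (item.split(":") for item in val.split(","))
            }
        elif key == "marker_specs":
            kwargs[key] = tuple(
                (p.strip(), float(a)) for p, a in (item.split(":") for item in val.split(","))
            ) if val else ()
        elif key in _TUPLE_KEYS:
            a, b = val.split(",")
            cast = int if key == "peptides_per_protein" else float
            kwargs[key] = (cast(a), cast(b))
        elif key in _INT_KEYS:
            kwargs[key] = int(val)
        else:
            kwargs[key] = float(val)
    return SimulationConfig(**kwargs)
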