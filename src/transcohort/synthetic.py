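"""Paired-cohort synthetic expression data with known planted structure.

Every downstream stage of the pipeline is exercised against data from this
generator, which emulates the structure of a two-cohort breast-cancer
profiling study:

* groups of correlated genes/miRNAs ("modules"), each driven by a single
  latent factor per cohort: ``x = loading * f + noise_sd * eps`` so the
  within-module pairwise Pearson correlation is
  ``loading**2 / (loading**2 + noise_sd**2)``;
* four intrinsic-subtype centroids applied over a 45-gene panel mirroring
  the usable PAM50 genes (luminal A/B, HER2-enriched, basal-like);
* bimodal ER (ESR1) and HER2 (ERBB2) marker distributions, two modes
  separated by ``marker_separation`` log2 units;
* planted high-average ECM1/ECM3 submatrices (gene rows x sample columns);
* an additive cohort batch shift (optional) and a storage-time covariate
  affecting a small designated gene fraction;
* per-probe detection p-values with a designated undetected fraction.

One seeded :class:`numpy.random.Generator` is threaded through all draws;
identical configs (including seed) give bitwise-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, GeneSet, TranscohortError
from . import panels
from .io import write_expression_tsv, write_gmt

__all__ = [
    "ModuleSpec",
    "SimulationConfig",
    "GroundTruth",
    "generate_cohort_pair",
    "generate_detection_p",
    "write_fixture",
]


@dataclass(frozen=True)
class ModuleSpec:
    """One planted correlated-gene module.

    ``subtype_link`` ties half the latent factor's variance to a subtype
    covariate ("er" or "proliferation"), emulating the ER and
    proliferation-related co-expression clusters of breast tumors; the
    within-module pairwise correlation is unchanged because the factor
    keeps unit variance.
    """

    size: int
    latent_loading: float = 0.9
    shared_across_cohorts: bool = True
    subtype_link: str | None = None

    def __post_init__(self):
        if self.size <= 0:
            raise TranscohortError("module size must be positive")
        if not (0 < self.latent_loading <= 1):
            raise TranscohortError("latent_loading must lie in (0, 1]")
        if self.subtype_link not in (None, "er", "proliferation"):
            raise TranscohortError("subtype_link must be None, 'er' or 'proliferation'")


def _default_modules() -> list[ModuleSpec]:
    # ten shared + two cohort-private modules of realistic sizes; the two
    # largest mirror the ER and proliferation co-expression clusters
    mods = [ModuleSpec(40, 0.9, True, "er"), ModuleSpec(35, 0.9, True, "proliferation")]
    mods += [ModuleSpec(s, 0.9, True) for s in (30, 25, 25, 20, 20, 15, 15, 12)]
    mods += [ModuleSpec(15, 0.9, False), ModuleSpec(12, 0.9, False)]
    return mods


def _default_mirna_modules() -> list[ModuleSpec]:
    return [ModuleSpec(s, 0.85, True) for s in (12, 10, 8, 6, 5)] + [ModuleSpec(6, 0.85, False)]


@dataclass
class SimulationConfig:
    """Parameters of the two-cohort generator (defaults = study conditions)."""

    n_samples_per_cohort: int = 100
    n_genes: int = 2000
    n_mirnas: int = 300
    modules: list[ModuleSpec] = field(default_factory=_default_modules)
    mirna_modules: list[ModuleSpec] = field(default_factory=_default_mirna_modules)
    subtype_mixture: dict[str, float] = field(
        default_factory=lambda: {"LumA": 0.35, "LumB": 0.25, "ERBB2": 0.2, "Basal": 0.2}
    )
    subtype_separation: float = 2.0  # log2 distance between subtype modes per panel gene
    marker_separation: float = 4.0  # log2 distance between bimodal marker modes
    ecm3_block: tuple[int, int, float] = (25, 25, 2.0)  # (n_rows, n_cols, shift)
    ecm1_block: tuple[int, int, float] = (20, 20, 2.0)
    batch_shift: float = 0.0
    storage_effect: tuple[int, float] = (6, 0.5)  # (n_genes_affected, slope per hour)
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        tot = sum(self.subtype_mixture.values())
        if abs(tot - 1.0) > 1e-9:
            raise TranscohortError(f"subtype_mixture sums to {tot}, not 1")
        if set(self.subtype_mixture) != set(panels.INTRINSIC_SUBTYPES):
            raise TranscohortError("subtype_mixture must cover LumA/LumB/ERBB2/Basal")
        for name in ("n_samples_per_cohort", "n_genes", "n_mirnas"):
            if getattr(self, name) <= 0:
                raise TranscohortError(f"{name} must be positive")
        if self.noise_sd <= 0:
            raise TranscohortError("noise_sd must be > 0")
        self.modules = [m if isinstance(m, ModuleSpec) else ModuleSpec(*m) for m in self.modules]
        self.mirna_modules = [
            m if isinstance(m, ModuleSpec) else ModuleSpec(*m) for m in self.mirna_modules
        ]
        reserved = (
            len(panels.PAM50_USABLE)
            + len(panels.claudin_low_panel().members)
            + self.ecm3_block[0]
            + self.ecm1_block[0]
        )
        if reserved + sum(m.size for m in self.modules) > self.n_genes:
            raise TranscohortError(
                f"module sizes + reserved panel/ECM genes ({reserved}) exceed n_genes"
            )
        if sum(m.size for m in self.mirna_modules) + 36 > self.n_mirnas:
            raise TranscohortError(
                "miRNA module sizes + 36 reserved subtype-tracking miRNAs exceed n_mirnas")
        if self.storage_effect[0] > self.n_genes:
            raise TranscohortError("storage_effect gene count exceeds n_genes")


@dataclass
class GroundTruth:
    """Planted structure, recoverable by id."""

    module_membership: dict[str, int]
    mirna_module_membership: dict[str, int]
    shared_modules: list[int]
    subtype_labels: dict[str, dict[str, str]]  # cohort -> sample -> label
    er_status: dict[str, dict[str, bool]]
    ecm_rows: dict[str, list[str]]  # "ECM1"/"ECM3" -> gene ids
    ecm_cols: dict[str, dict[str, list[str]]]  # cohort -> label -> sample ids
    storage_genes: list[str]
    storage_hours: dict[str, dict[str, float]]
    thresholds: dict[str, float]  # marker gene -> true bimodal cut
    claudin_low: dict[str, list[str]] = field(default_factory=dict)


def _gene_layout(config: SimulationConfig):
    """Assign feature ids: panel, claudin, ECM blocks, modules, background."""
    claudin = sorted(panels.claudin_low_panel().members)
    ids: list[str] = list(panels.PAM50_USABLE) + claudin
    n3, _, _ = config.ecm3_block
    n1, _, _ = config.ecm1_block
    ecm3 = list(panels.ECM3_SEED[: min(len(panels.ECM3_SEED), n3)])
    ecm3 += [f"ECM3F{i:04d}" for i in range(n3 - len(ecm3))]
    ecm1 = list(panels.ECM1_SEED[: min(len(panels.ECM1_SEED), n1)])
    ecm1 += [f"ECM1F{i:04d}" for i in range(n1 - len(ecm1))]
    ids += ecm3 + ecm1
    module_ids: dict[int, list[str]] = {}
    k = 0
    for mi, mod in enumerate(config.modules):
        module_ids[mi] = [f"MOD{mi:02d}G{j:03d}" for j in range(mod.size)]
        ids += module_ids[mi]
        k += mod.size
    n_bg = config.n_genes - len(ids)
    ids += [f"BG{i:05d}" for i in range(n_bg)]
    return ids, ecm3, ecm1, module_ids


def _simulate_cohort(config, rng, ids, ecm3, ecm1, module_ids, baselines, cohort):
    n = config.n_samples_per_cohort
    sd = config.noise_sd
    samples = [f"{cohort}{i:04d}" for i in range(n)]
    idx = {g: i for i, g in enumerate(ids)}
    X = baselines[:, None] + sd * rng.standard_normal((len(ids), n))

    # subtype labels and marker status
    names = list(config.subtype_mixture)
    probs = np.array([config.subtype_mixture[k] for k in names])
    labels = rng.choice(names, size=n, p=probs)
    er_pos = np.isin(labels, ["LumA", "LumB"])

    # intrinsic centroid over the panel (markers handled separately)
    cent = panels.intrinsic_centroid_patterns()
    amp = config.subtype_separation / 2.0
    for g in panels.PAM50_USABLE:
        if g in ("ESR1", "ERBB2"):
            continue
        X[idx[g]] += amp * cent.loc[g, labels].to_numpy()

    # bimodal markers: two modes marker_separation apart
    X[idx["ESR1"]] += config.marker_separation * er_pos
    X[idx["ERBB2"]] += config.marker_separation * (labels == "ERBB2")

    # claudin-low structure: a small fraction of Basal samples lose the
    # epithelial block and gain the mesenchymal block
    claudin_lo = np.zeros(n, dtype=bool)
    basal_idx = np.flatnonzero(labels == "Basal")
    n_cl = max(1, int(round(0.15 * basal_idx.size))) if basal_idx.size else 0
    if n_cl:
        claudin_lo[rng.choice(basal_idx, size=n_cl, replace=False)] = True
    for g in panels.CLAUDIN_EPITHELIAL:
        X[idx[g]] += 1.0 - 2.0 * claudin_lo  # high epithelial unless claudin-low
    for g in panels.CLAUDIN_MESENCHYMAL:
        X[idx[g]] += 2.0 * claudin_lo

    # correlated modules: latent factor per module per cohort; linked
    # factors put half their variance on a standardized subtype covariate
    prolif_level = {"LumA": -1.0, "LumB": 1.0, "ERBB2": 0.5, "Basal": 1.0}
    for mi, mod in enumerate(config.modules):
        f = rng.standard_normal(n)
        if mod.subtype_link is not None:
            s = (2.0 * er_pos - 1.0 if mod.subtype_link == "er"
                 else np.array([prolif_level[lab] for lab in labels]))
            sd_s = s.std()
            if sd_s > 0:
                z = (s - s.mean()) / sd_s
                f = np.sqrt(0.5) * z + np.sqrt(0.5) * f
        if not mod.shared_across_cohorts:
            # cohort-private: planted only in cohort A; independent noise in B
            if cohort != "A":
                continue
        rows = [idx[g] for g in module_ids[mi]]
        X[rows] = (
            baselines[rows][:, None]
            + mod.latent_loading * f[None, :]
            + sd * rng.standard_normal((len(rows), n))
        )

    # ECM blocks: +shift on planted rows x planted columns; ECM3 columns
    # drawn preferentially from ER-positive samples, ECM1 from ER-negative
    ecm_cols = {}
    for label, rows_ids, (_, n_cols, shift), pool_mask in (
        ("ECM3", ecm3, config.ecm3_block, er_pos),
        ("ECM1", ecm1, config.ecm1_block, ~er_pos),
    ):
        pool = np.flatnonzero(pool_mask)
        others = np.flatnonzero(~pool_mask)
        take = min(n_cols, pool.size)
        cols = list(rng.choice(pool, size=take, replace=False))
        if take < n_cols:
            cols += list(rng.choice(others, size=n_cols - take, replace=False))
        cols = np.array(sorted(cols))
        rows = [idx[g] for g in rows_ids]
        X[np.ix_(rows, cols)] += shift
        ecm_cols[label] = [samples[c] for c in cols]

    # storage-time covariate on a designated small gene fraction
    hours = rng.uniform(1.0, 4.0, size=n)
    n_aff, slope = config.storage_effect
    storage_genes = [f"BG{i:05d}" for i in range(min(n_aff, config.n_genes))]
    for g in storage_genes:
        if g in idx:
            X[idx[g]] += slope * hours

    if cohort == "B":
        X = X + config.batch_shift

    values = pd.DataFrame(X, index=ids, columns=samples)
    meta = {
        "labels": dict(zip(samples, labels.tolist())),
        "er": dict(zip(samples, er_pos.tolist())),
        "ecm_cols": ecm_cols,
        "hours": dict(zip(samples, hours.tolist())),
        "storage_genes": storage_genes,
        "claudin_low": [s for s, c in zip(samples, claudin_lo) if c],
    }
    return ExpressionDataset(values=values, cohort=cohort), meta


def generate_cohort_pair(config: SimulationConfig):
    """Generate the two gene-level cohorts and the planted ground truth.

    Returns ``(cohort_a, cohort_b, truth)``.  Shared modules have identical
    membership in both cohorts but independent latent-factor draws; private
    modules exist only in cohort A.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ids, ecm3, ecm1, module_ids = _gene_layout(config)
    baselines = rng.normal(8.0, 1.0, size=len(ids))
    ds_a, meta_a = _simulate_cohort(config, rng, ids, ecm3, ecm1, module_ids, baselines, "A")
    ds_b, meta_b = _simulate_cohort(config, rng, ids, ecm3, ecm1, module_ids, baselines, "B")
    membership = {g: mi for mi, gs in module_ids.items() for g in gs}
    base = dict(zip(ids, baselines))
    truth = GroundTruth(
        module_membership=membership,
        mirna_module_membership={},
        shared_modules=[mi for mi, m in enumerate(config.modules) if m.shared_across_cohorts],
        subtype_labels={"A": meta_a["labels"], "B": meta_b["labels"]},
        er_status={"A": meta_a["er"], "B": meta_b["er"]},
        ecm_rows={"ECM3": ecm3, "ECM1": ecm1},
        ecm_cols={"A": meta_a["ecm_cols"], "B": meta_b["ecm_cols"]},
        storage_genes=meta_a["storage_genes"],
        storage_hours={"A": meta_a["hours"], "B": meta_b["hours"]},
        thresholds={
            "ESR1": base["ESR1"] + config.marker_separation / 2.0,
            "ERBB2": base["ERBB2"] + config.marker_separation / 2.0,
        },
        claudin_low={"A": meta_a["claudin_low"], "B": meta_b["claudin_low"]},
    )
    return ds_a, ds_b, truth


def generate_mirna_pair(config: SimulationConfig, subtype_labels=None):
    """Generate the paired miRNA matrices.

    Besides the planted correlated modules, three small groups of miRNAs
    track the intrinsic subtypes (luminal-, proliferation- and basal-
    associated), emulating the observation that global miRNA profiles group
    by molecular subtype rather than cohort.  ``subtype_labels`` maps
    cohort -> sample -> subtype; when omitted, labels are drawn from the
    configured mixture.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_samples_per_cohort
    sd = config.noise_sd
    ids: list[str] = []
    module_ids: dict[int, list[str]] = {}
    for mi, mod in enumerate(config.mirna_modules):
        module_ids[mi] = [f"MIRMOD{mi:02d}M{j:03d}" for j in range(mod.size)]
        ids += module_ids[mi]
    n_sub_group = 12
    sub_groups = {
        "lum": [f"MIRLUM{i:03d}" for i in range(n_sub_group)],
        "prolif": [f"MIRPRO{i:03d}" for i in range(n_sub_group)],
        "basal": [f"MIRBAS{i:03d}" for i in range(n_sub_group)],
    }
    for gs in sub_groups.values():
        ids += gs
    ids += [f"MIRBG{i:04d}" for i in range(config.n_mirnas - len(ids))]
    baselines = rng.normal(6.0, 1.0, size=len(ids))
    idx = {g: i for i, g in enumerate(ids)}
    names = list(config.subtype_mixture)
    probs = np.array([config.subtype_mixture[k] for k in names])
    amp = config.subtype_separation / 2.0
    effect = {  # per subtype, additive shift of each miRNA group
        "LumA": {"lum": amp, "prolif": -amp, "basal": -amp},
        "LumB": {"lum": amp, "prolif": amp, "basal": -amp},
        "ERBB2": {"lum": -amp, "prolif": amp / 2, "basal": -amp},
        "Basal": {"lum": -amp, "prolif": amp, "basal": amp},
    }
    out = []
    for cohort in ("A", "B"):
        samples = [f"{cohort}{i:04d}" for i in range(n)]
        X = baselines[:, None] + sd * rng.standard_normal((len(ids), n))
        if subtype_labels is not None:
            labels = np.array([subtype_labels[cohort][s] for s in samples])
        else:
            labels = rng.choice(names, size=n, p=probs)
        for gname, gs in sub_groups.items():
            shift = np.array([effect[lab][gname] for lab in labels])
            for g in gs:
                X[idx[g]] += shift
        for mi, mod in enumerate(config.mirna_modules):
            f = rng.standard_normal(n)
            if not mod.shared_across_cohorts and cohort != "A":
                continue
            rows = [idx[g] for g in module_ids[mi]]
            X[rows] = (
                baselines[rows][:, None]
                + mod.latent_loading * f[None, :]
                + sd * rng.standard_normal((len(rows), n))
            )
        if cohort == "B":
            X = X + config.batch_shift
        out.append(ExpressionDataset(pd.DataFrame(X, index=ids, columns=samples), cohort=cohort))
    membership = {g: mi for mi, gs in module_ids.items() for g in gs}
    return out[0], out[1], membership


def generate_detection_p(dataset: ExpressionDataset, frac_undetected: float,
                         seed: int = 0) -> pd.DataFrame:
    """Construct a detection-p matrix with a designated undetected fraction.

    ``round(frac_undetected * n_features)`` features receive p >= 0.01 in
    every sample (they fail the downstream detection filter); all others get
    p < 0.01 in at least one sample.
    """
    if not (0 <= frac_undetected < 1):
        raise TranscohortError("frac_undetected must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    m, n = dataset.values.shape
    n_fail = int(round(frac_undetected * m))
    fail = np.zeros(m, dtype=bool)
    if n_fail:
        fail[rng.choice(m, size=n_fail, replace=False)] = True
    P = rng.uniform(0.0, 1.0, size=(m, n))
    # detected features: guarantee one sample below 0.01, scale the rest up
    P[~fail] = 0.01 + 0.99 * P[~fail]
    if n - 0 > 0:
        det_rows = np.flatnonzero(~fail)
        cols = rng.integers(0, n, size=det_rows.size)
        P[det_rows, cols] = rng.uniform(0.0, 0.0099, size=det_rows.size)
    P[fail] = 0.01 + 0.99 * rng.uniform(0.0, 1.0, size=(n_fail, n))
    return pd.DataFrame(P, index=dataset.values.index, columns=dataset.values.columns)


def write_fixture(datasets, truth: GroundTruth, directory) -> list[Path]:
    """Write TSV matrices, sample annotation, truth JSON and panel GMTs.

    ``datasets`` maps a name (e.g. ``"gene_A"``) to an ExpressionDataset.
    Read-back through :func:`transcohort.io.read_expression_tsv` reproduces
    the values to full precision.
    """
    directory = Path(directory)
    for name, ds in datasets.items():
        if ds.n_features == 0 or ds.n_samples == 0:
            raise TranscohortError(f"dataset {name!r} is empty; nothing written")
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, ds in datasets.items():
        p = directory / f"{name}_expression.tsv"
        dp = directory / f"{name}_detection_p.tsv" if ds.detection_p is not None else None
        write_expression_tsv(ds, p, detection_path=dp)
        written.append(p)
        if dp:
            written.append(dp)
    # sample annotation
    rows = []
    for cohort, labels in truth.subtype_labels.items():
        for s, lab in labels.items():
            er = truth.er_status[cohort][s]
            rows.append({
                "sample_id": s,
                "cohort": cohort,
                "age": "",
                "er_ihc": "pos" if er else "neg",
                "pr_ihc": "pos" if er else "neg",
                "her2_ihc": "pos" if lab == "ERBB2" else "neg",
                "storage_hours": truth.storage_hours[cohort][s],
                "true_subtype": lab,
            })
    ann_path = directory / "sample_annotation.tsv"
    pd.DataFrame(rows).to_csv(ann_path, sep="\t", index=False)
    written.append(ann_path)
    truth_path = directory / "truth.json"
    truth_path.write_text(json.dumps(asdict(truth), indent=1))
    written.append(truth_path)
    gmt_path = directory / "panels.gmt"
    write_gmt(
        [panels.pam50_panel(), panels.claudin_low_panel(),
         panels.ecm1_seed_set(), panels.ecm3_seed_set(),
         GeneSet("ECM_UNIVERSE", "planted ECM rows",
                 frozenset(truth.ecm_rows["ECM1"]) | frozenset(truth.ecm_rows["ECM3"]))],
        gmt_path,
    )
    written.append(gmt_path)
    return written
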