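"""Synthetic multi-omic cohorts with planted association modules.

The generator emulates the statistical structure the discovery pipeline
assumes: tumor/adjacent-normal sample pairs; chromosome-arm-coherent copy
number (one latent arm signal shared by the arm's probes plus probe noise);
genes whose expression log-ratio is driven positively by their own arm's
CNV (cis), by regulator genes on another arm (trans), or negatively by the
methylation state of effector genes; and validation cohorts with
right-censored survival times whose hazard depends on a planted module's
median expression only in designated subpopulations (the testable analogue
of gender/ethnicity-specific prognostic effects).

Planted effect sizes are expressed on a standardized driver scale: with
``beta = 1`` and ``noise_sd = 1`` the latent target-driver correlation is
1/sqrt(2) ~ 0.707, the middle of the screening regime.  Every draw is a
pure function of :class:`SimulationSpec` (seed included).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import CohortBundle, OmicsMatrix, validate_annotation, write_clinical, write_matrix_tsv


@dataclass
class PlantedModule:
    """One planted module: effector, targets, effect size and survival link.

    ``gamma`` maps validation-cohort names to the log-hazard multiplier
    applied to the module's standardized median expression (0 = no
    prognostic effect in that cohort).
    """

    kind: str  # cis_cnv | trans_cnv | methylation
    effector: str | tuple[str, ...]  # arm id, or methylation effector gene ids
    n_targets: int = 40
    beta: float = 1.0
    noise_sd: float = 1.0
    gamma: dict[str, float] = field(default_factory=dict)
    n_regulators: int = 5  # trans only
    regulator_noise_sd: float = 0.5  # trans only


@dataclass
class CohortSpec:
    name: str
    n_samples: int
    gender: str = "unknown"
    ethnicity: str = ""


@dataclass
class SimulationSpec:
    """All parameters of one synthetic study (training + validation)."""

    seed: int = 0
    n_chromosomes: int = 20
    genes_per_arm: int = 50
    n_train_samples: int = 60
    cnv_probes_per_arm: int = 10
    sigma_arm: float = 1.0
    probe_noise_sd: float = 0.3
    n_methylation_genes: int = 100
    background_sd: float = 1.0
    planted: list[PlantedModule] = field(default_factory=list)
    validation_cohorts: list[CohortSpec] = field(default_factory=list)
    baseline_hazard: float = 0.1
    censoring_fraction: float = 0.3
    survival_dist: str = "exponential"  # or "weibull"
    weibull_shape: float = 1.5

    @property
    def n_genes(self) -> int:
        return self.n_chromosomes * 2 * self.genes_per_arm

    def arms(self) -> list[str]:
        return [f"chr{c}{a}" for c in range(1, self.n_chromosomes + 1) for a in ("p", "q")]

    def validate(self) -> None:
        if self.n_chromosomes <= 0 or self.genes_per_arm <= 0 or self.n_train_samples <= 0:
            raise ValueError("layout counts must be positive")
        if not 0.0 <= self.censoring_fraction < 1.0:
            raise ValueError("censoring_fraction must lie in [0, 1)")
        if self.survival_dist not in ("exponential", "weibull"):
            raise ValueError(f"unknown survival_dist {self.survival_dist!r}")
        arms = set(self.arms())
        cohort_names = {c.name for c in self.validation_cohorts}
        for pm in self.planted:
            if pm.kind in ("cis_cnv", "trans_cnv") and pm.effector not in arms:
                raise ValueError(f"planted effector arm {pm.effector!r} not in layout")
            if pm.kind == "cis_cnv" and pm.n_targets > self.genes_per_arm:
                raise ValueError(
                    f"arm {pm.effector!r} has {self.genes_per_arm} genes < {pm.n_targets} targets"
                )
            unknown = set(pm.gamma) - cohort_names
            if unknown:
                raise ValueError(f"gamma refers to undeclared cohorts: {sorted(unknown)}")


@dataclass
class PlantedTruth:
    """Ground truth of the planted modules, for recovery scoring."""

    modules: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.modules, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(modules=json.load(fh))


def default_spec(seed: int = 0) -> SimulationSpec:
    """The default study conditions: one planted cis module on chr1p whose
    survival effect exists only in the East-Asian female cohort."""
    return SimulationSpec(
        seed=seed,
        planted=[
            PlantedModule(
                kind="cis_cnv",
                effector="chr1p",
                n_targets=40,
                beta=1.0,
                noise_sd=1.0,
                gamma={"EastAsian-female": 1.2, "EastAsian-male": 0.0},
            )
        ],
        validation_cohorts=[
            CohortSpec("EastAsian-female", 150, gender="female", ethnicity="EastAsian"),
            CohortSpec("EastAsian-male", 150, gender="male", ethnicity="EastAsian"),
        ],
    )


def null_spec(seed: int = 0, n_samples: int = 150, cohort_name: str = "null-cohort") -> SimulationSpec:
    """Fully null conditions: no planted modules, no survival effects."""
    return SimulationSpec(
        seed=seed,
        planted=[],
        validation_cohorts=[CohortSpec(cohort_name, n_samples)],
    )


# ---------------------------------------------------------------------------
# layout helpers
# ---------------------------------------------------------------------------

def make_annotation(spec: SimulationSpec) -> pd.DataFrame:
    """Gene + CNV-probe annotation (chromosome, arm, position) for the layout."""
    rows = []
    gid = 0
    for c in range(1, spec.n_chromosomes + 1):
        for arm in ("p", "q"):
            for j in range(spec.genes_per_arm):
                gid += 1
                rows.append(
                    {
                        "gene_id": f"G{gid:04d}",
                        "chromosome": str(c),
                        "arm": arm,
                        "position": (j + 1) * 1_000_000,
                    }
                )
            for j in range(spec.cnv_probes_per_arm):
                rows.append(
                    {
                        "gene_id": f"P_chr{c}{arm}_{j:02d}",
                        "chromosome": str(c),
                        "arm": arm,
                        "position": (j + 1) * 1_000_000 + 500_000,
                    }
                )
    return validate_annotation(pd.DataFrame(rows))


def _genes_by_arm(spec: SimulationSpec) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    gid = 0
    for c in range(1, spec.n_chromosomes + 1):
        for arm in ("p", "q"):
            label = f"chr{c}{arm}"
            out[label] = [f"G{gid + j + 1:04d}" for j in range(spec.genes_per_arm)]
            gid += spec.genes_per_arm
    return out


def _planted_targets(spec: SimulationSpec, rng: np.random.Generator) -> list[dict]:
    """Resolve each planted module to explicit effector/regulator/target ids."""
    by_arm = _genes_by_arm(spec)
    all_genes = [g for arm in by_arm.values() for g in arm]
    meth_genes = _methylation_genes(spec)
    taken: set[str] = set()
    resolved = []
    for pm in spec.planted:
        if pm.kind == "cis_cnv":
            pool = [g for g in by_arm[pm.effector] if g not in taken]
            targets = pool[: pm.n_targets]
            regulators: list[str] = []
            effectors = [pm.effector]
        elif pm.kind == "trans_cnv":
            reg_pool = [g for g in by_arm[pm.effector] if g not in taken]
            regulators = reg_pool[: pm.n_regulators]
            off_arm = [g for g in all_genes if g not in by_arm[pm.effector] and g not in taken]
            targets = list(rng.choice(off_arm, size=pm.n_targets, replace=False))
            effectors = [pm.effector]
        elif pm.kind == "methylation":
            effectors = list(pm.effector) if not isinstance(pm.effector, str) else [pm.effector]
            for e in effectors:
                if e not in meth_genes:
                    raise ValueError(f"methylation effector {e!r} is not a methylation-measured gene")
            others = [g for g in all_genes if g not in effectors and g not in taken]
            extra = list(rng.choice(others, size=max(0, pm.n_targets - len(effectors)), replace=False))
            targets = sorted(effectors) + extra
            regulators = []
        else:
            raise ValueError(f"unknown planted module kind {pm.kind!r}")
        if len(targets) < pm.n_targets:
            raise ValueError(f"effector {pm.effector!r}: not enough free genes for {pm.n_targets} targets")
        taken.update(targets)
        taken.update(regulators)
        resolved.append(
            {
                "kind": pm.kind,
                "effectors": effectors,
                "regulators": regulators,
                "targets": sorted(targets),
                "gamma": dict(pm.gamma),
                "beta": pm.beta,
                "noise_sd": pm.noise_sd,
                "regulator_noise_sd": pm.regulator_noise_sd,
            }
        )
    return resolved


def _methylation_genes(spec: SimulationSpec) -> list[str]:
    n = spec.n_genes
    k = min(spec.n_methylation_genes, n)
    step = max(1, n // k)
    ids = [f"G{i + 1:04d}" for i in range(0, n, step)][:k]
    return ids


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else v - v.mean()


# ---------------------------------------------------------------------------
# training cohort
# ---------------------------------------------------------------------------

def simulate_training_cohort(spec: SimulationSpec) -> tuple[CohortBundle, PlantedTruth]:
    """Tumor + adjacent-normal matrices for expression, CNV probes, methylation.

    The annotation table covers both genes and CNV probes, so arm-level CNV
    aggregation and cis/trans assignment run off one table.  Deterministic
    under ``spec.seed``.
    """
    spec.validate()
    root = np.random.SeedSequence([spec.seed, 11])
    rng_layout, rng_arm, rng_expr, rng_cnv, rng_meth = (
        np.random.default_rng(s) for s in root.spawn(5)
    )
    n = spec.n_train_samples
    samples = [f"T{i + 1:03d}" for i in range(n)]
    annotation = make_annotation(spec)
    arms = spec.arms()
    by_arm = _genes_by_arm(spec)
    genes = [g for a in arms for g in by_arm[a]]
    gene_pos = {g: i for i, g in enumerate(genes)}
    truth_modules = _planted_targets(spec, rng_layout)

    # latent arm CNV signals, shared by the arm's probes
    arm_sig = rng_arm.normal(0.0, spec.sigma_arm, size=(len(arms), n))
    arm_driver = {a: _standardize(arm_sig[i]) for i, a in enumerate(arms)}

    # expression log-ratios: independent background, then planted structure
    logratio = rng_expr.normal(0.0, spec.background_sd, size=(len(genes), n))
    meth_genes = _methylation_genes(spec)
    meth_diff = rng_meth.normal(0.0, 0.02, size=(len(meth_genes), n))
    meth_row = {g: i for i, g in enumerate(meth_genes)}

    for tm in truth_modules:
        beta, noise = tm["beta"], tm["noise_sd"]
        if tm["kind"] == "cis_cnv":
            driver = arm_driver[tm["effectors"][0]]
            for g in tm["targets"]:
                logratio[gene_pos[g]] = beta * driver + rng_expr.normal(0, noise, n)
        elif tm["kind"] == "trans_cnv":
            driver = arm_driver[tm["effectors"][0]]
            reg_rows = []
            for g in tm["regulators"]:
                row = beta * driver + rng_expr.normal(0, tm["regulator_noise_sd"], n)
                logratio[gene_pos[g]] = row
                reg_rows.append(row)
            reg_signal = _standardize(np.mean(reg_rows, axis=0))
            for g in tm["targets"]:
                sign = 1 if rng_layout.random() < 0.5 else -1
                logratio[gene_pos[g]] = sign * beta * reg_signal + rng_expr.normal(0, noise, n)
        else:  # methylation
            u = rng_meth.uniform(-0.35, 0.35, size=n)
            s = _standardize(u)
            for e in tm["effectors"]:
                meth_diff[meth_row[e]] = u + rng_meth.normal(0, 0.05, n)
            for g in tm["targets"]:
                logratio[gene_pos[g]] = -beta * s + rng_expr.normal(0, noise, n)

    expr_normal = np.exp(rng_expr.normal(0.0, 0.1, size=logratio.shape))
    expr_tumor = expr_normal * np.exp(logratio)

    probe_ids = []
    probe_log = []
    for i, arm in enumerate(arms):
        for j in range(spec.cnv_probes_per_arm):
            probe_ids.append(f"P_{arm}_{j:02d}")
            probe_log.append(arm_sig[i] + rng_cnv.normal(0.0, spec.probe_noise_sd, n))
    cnv_normal = np.exp(rng_cnv.normal(0.0, 0.05, size=(len(probe_ids), n)))
    cnv_tumor = cnv_normal * np.exp(np.vstack(probe_log))

    meth_normal = rng_meth.uniform(0.40, 0.50, size=(len(meth_genes), n))
    meth_tumor = np.clip(meth_normal + meth_diff, 0.005, 0.995)

    def _m(role, ids, vals):
        return OmicsMatrix(role=role, data=pd.DataFrame(vals, index=ids, columns=samples))

    bundle = CohortBundle(
        name="training",
        matrices={
            "expression_tumor": _m("expression", genes, expr_tumor),
            "expression_normal": _m("expression", genes, expr_normal),
            "cnv_tumor": _m("cnv_probe", probe_ids, cnv_tumor),
            "cnv_normal": _m("cnv_probe", probe_ids, cnv_normal),
            "methylation_tumor": _m("methylation", meth_genes, meth_tumor),
            "methylation_normal": _m("methylation", meth_genes, meth_normal),
        },
        clinical=None,
        annotation=annotation,
    )
    return bundle, PlantedTruth(modules=truth_modules)


# ---------------------------------------------------------------------------
# validation cohorts with survival
# ---------------------------------------------------------------------------

def _calibrate_censor_rate(rates: np.ndarray, target: float) -> float:
    """Censoring rate giving an expected censored fraction ``target`` when
    both event and censor times are exponential."""
    if target <= 0:
        return 0.0

    def frac(lc: float) -> float:
        return float(np.mean(lc / (lc + rates)))

    lo, hi = 1e-12, 1e12
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def simulate_validation_cohorts(spec: SimulationSpec) -> tuple[list[CohortBundle], PlantedTruth]:
    """Expression + survival cohorts with subpopulation-specific hazards.

    Per cohort, each planted module's targets share a latent factor (the
    same effect size as in training); survival times are exponential (or
    Weibull by flag) with log-hazard sum_m gamma_m[cohort] * standardized
    median target expression, independently censored at the configured
    fraction.
    """
    spec.validate()
    root = np.random.SeedSequence([spec.seed, 22])
    rng_layout = np.random.default_rng(root.spawn(1)[0])
    truth_modules = _planted_targets(spec, rng_layout)
    annotation = make_annotation(spec)
    genes = [g for a in spec.arms() for g in _genes_by_arm(spec)[a]]
    gene_pos = {g: i for i, g in enumerate(genes)}

    bundles = []
    for ci, cohort in enumerate(spec.validation_cohorts):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 33, ci]))
        n = cohort.n_samples
        sample_ids = [f"{cohort.name}_S{i + 1:03d}" for i in range(n)]
        expr = rng.normal(0.0, spec.background_sd, size=(len(genes), n))
        log_hazard = np.zeros(n)
        for tm in truth_modules:
            f = rng.normal(0.0, 1.0, size=n)
            for g in tm["targets"]:
                expr[gene_pos[g]] = tm["beta"] * f + rng.normal(0, tm["noise_sd"], n)
            gamma = float(tm["gamma"].get(cohort.name, 0.0))
            if gamma != 0.0:
                score = np.median(expr[[gene_pos[g] for g in tm["targets"]]], axis=0)
                log_hazard += gamma * _standardize(score)

        rates = spec.baseline_hazard * np.exp(log_hazard)
        t_event = rng.exponential(1.0 / rates)
        lc = _calibrate_censor_rate(rates, spec.censoring_fraction)
        t_censor = rng.exponential(1.0 / lc, size=n) if lc > 0 else np.full(n, np.inf)
        if spec.survival_dist == "weibull":
            # common power transform preserves order and censoring status
            k = spec.weibull_shape
            t_event, t_censor = t_event ** (1.0 / k), t_censor ** (1.0 / k)
        event = t_event <= t_censor
        time = np.minimum(t_event, t_censor)

        clinical = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "time": time,
                "event": event,
                "gender": cohort.gender,
                "cohort": cohort.name,
            }
        ).set_index("sample_id", drop=False)
        bundles.append(
            CohortBundle(
                name=cohort.name,
                matrices={
                    "expression": OmicsMatrix(
                        role="expression",
                        data=pd.DataFrame(expr, index=genes, columns=sample_ids),
                    )
                },
                clinical=clinical,
                annotation=annotation,
            )
        )
    return bundles, PlantedTruth(modules=truth_modules)


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

def score_recovery(modules, truth: PlantedTruth) -> pd.DataFrame:
    """Best-Jaccard match of inferred modules against each planted module.

    Returns one row per planted module with precision = |intersection| /
    |inferred targets| and recall = |intersection| / |planted targets|.
    """
    rows = []
    for tm in truth.modules:
        t_set = set(tm["targets"])
        best = None
        best_j = -1.0
        for m in modules:
            m_set = set(m.targets)
            inter = len(t_set & m_set)
            union = len(t_set | m_set)
            j = inter / union if union else 0.0
            if j > best_j:
                best, best_j = m, j
        if best is None or best_j <= 0.0:
            rows.append(
                {
                    "effector": ";".join(tm["effectors"]), "kind": tm["kind"],
                    "matched_module": None, "jaccard": 0.0,
                    "precision": 0.0, "recall": 0.0,
                }
            )
            continue
        inter = len(t_set & set(best.targets))
        rows.append(
            {
                "effector": ";".join(tm["effectors"]), "kind": tm["kind"],
                "matched_module": best.module_id, "jaccard": best_j,
                "precision": inter / len(best.targets),
                "recall": inter / len(t_set),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# disk layout
# ---------------------------------------------------------------------------

def write_cohort(bundle: CohortBundle, outdir) -> dict:
    """Write a cohort's matrices/annotation/clinical as TSVs; returns a
    ``load_cohort``-compatible config entry."""
    import os

    os.makedirs(outdir, exist_ok=True)
    entry: dict = {"name": bundle.name, "matrices": {}}
    for label, m in bundle.matrices.items():
        path = os.path.join(outdir, f"{label}.tsv")
        write_matrix_tsv(m, path)
        entry["matrices"][label] = {"path": path, "role": m.role}
    if bundle.annotation is not None:
        path = os.path.join(outdir, "annotation.tsv")
        bundle.annotation.to_csv(path, sep="\t", index=False)
        entry["annotation"] = path
    if bundle.clinical is not None:
        path = os.path.join(outdir, "clinical.tsv")
        write_clinical(bundle.clinical, path)
        entry["clinical"] = path
    return entry
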