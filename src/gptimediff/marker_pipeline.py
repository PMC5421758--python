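"""Five-test marker screen for treatment-insensitivity genes.

The screen contrasts drug-responsive cell lines against non-responsive ones
across a ragged time-course design (conditions sampled at different time
points).  Per probe, five GP likelihood-ratio tests are run:

  1. responsive vs non-responsive vehicle controls (pooled cell lines),
  2. responsive control vs responsive low dose,
  3. responsive control vs responsive high dose,
  4. non-responsive control vs non-responsive low dose,
  5. non-responsive control vs non-responsive high dose.

Benjamini-Hochberg FDR control is applied within each test across probes.
A probe is called a marker iff it passes test 1, passes at least one of
tests 2 and 3, and fails both tests 4 and 5 — i.e. the gene separates the
two groups at baseline and responds to the drug only in responsive lines.

Cell lines within a group are pooled as replicates of a single GP; cell-line
identity is not a model covariate.  Missing replicates are imputed once, up
front, by sampling a normal with the observed replicates' mean and standard
deviation, so all five tests see identical data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .difftest import bh_adjust, lr_test
from .gp_core import OptimizerSettings, PriorConfig, TimeCourseSet
from .simulate import sample_mean_function

logger = logging.getLogger("gptimediff")

ROLE_NAMES = (
    "responsive_control", "responsive_low", "responsive_high",
    "nonresponsive_control", "nonresponsive_low", "nonresponsive_high",
)

#: the five contrasts as (condition A role, condition B role)
TEST_CONTRASTS = (
    ("responsive_control", "nonresponsive_control"),
    ("responsive_control", "responsive_low"),
    ("responsive_control", "responsive_high"),
    ("nonresponsive_control", "nonresponsive_low"),
    ("nonresponsive_control", "nonresponsive_high"),
)

#: default responsiveness classification of the study's cell lines
RESPONSIVE_LINES = ("SKBR-3", "BT-474")
NONRESPONSIVE_LINES = ("MDA-MB-468", "T-47D")

#: available treatment time points per (cell line kind): the vehicle control
#: is sampled at 0/2/6/12/24 h; treated conditions at subsets
DEFAULT_GRIDS = {
    ("SKBR-3", "control"): (0, 2, 6, 12, 24),
    ("SKBR-3", "low"): (6, 12, 24),
    ("SKBR-3", "high"): (6, 12),
    ("BT-474", "control"): (0, 2, 6, 12, 24),
    ("BT-474", "low"): (2, 6, 12, 24),
    ("BT-474", "high"): (6, 12),
    ("T-47D", "control"): (0, 2, 6, 12, 24),
    ("T-47D", "low"): (2, 6, 12, 24),
    ("T-47D", "high"): (2, 6, 12),
    ("MDA-MB-468", "control"): (0, 2, 6, 12, 24),
    ("MDA-MB-468", "low"): (2, 6, 12, 24),
    ("MDA-MB-468", "high"): (2, 6, 12),
}


class ImputationError(ValueError):
    """Fewer than two observed replicate values: imputation refused."""


def _dose_level(dose: float) -> str:
    if dose == 0:
        return "control"
    return "low" if dose < 0.5 else "high"


@dataclass
class StudyDesign:
    """Maps every sample of the expression matrix to one of the six roles.

    ``sample_roles``: sample_id -> role name;
    ``sheet``: the sample sheet (sample_id, cell_line, treatment, dose_uM,
    time_h, replicate).
    """

    sample_roles: dict
    sheet: pd.DataFrame

    @classmethod
    def from_sample_sheet(cls, sheet: pd.DataFrame,
                          responsive_lines=RESPONSIVE_LINES,
                          nonresponsive_lines=NONRESPONSIVE_LINES) -> "StudyDesign":
        required = {"sample_id", "cell_line", "dose_uM", "time_h", "replicate"}
        missing = required - set(sheet.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        dup = sheet["sample_id"][sheet["sample_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate sample id(s): {sorted(dup.unique())}")
        roles = {}
        for _, row in sheet.iterrows():
            line = row["cell_line"]
            if line in responsive_lines:
                group = "responsive"
            elif line in nonresponsive_lines:
                group = "nonresponsive"
            else:
                raise ValueError(f"cell line {line!r} has no responsiveness class")
            roles[row["sample_id"]] = f"{group}_{_dose_level(float(row['dose_uM']))}"
        return cls(sample_roles=roles, sheet=sheet.reset_index(drop=True))

    def replicate_series(self, role: str):
        """Per (cell line, replicate) time series for a role: list of
        (grid, sample-id list) with samples ordered by time."""
        sub = self.sheet[[self.sample_roles[s] == role for s in self.sheet["sample_id"]]]
        out = []
        for (line, rep), grp in sub.groupby(["cell_line", "replicate"], sort=True):
            grp = grp.sort_values("time_h")
            out.append((grp["time_h"].to_numpy(dtype=float),
                        grp["sample_id"].tolist()))
        return out


@dataclass
class MarkerCall:
    """Per-probe outcomes of the five tests plus the combined selection."""

    probe_id: str
    p_values: np.ndarray        # length 5
    q_values: np.ndarray        # length 5
    passed: np.ndarray          # length-5 booleans
    selected: bool


def combine_selection(passed) -> bool:
    """The marker rule: pass 1, pass (2 or 3), fail 4 and fail 5."""
    p = np.asarray(passed, dtype=bool)
    if p.shape != (5,):
        raise ValueError("expected five pass/fail flags")
    return bool(p[0] and (p[1] or p[2]) and not p[3] and not p[4])


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute_missing_replicate(values, target_count: int, rng: np.random.Generator) -> np.ndarray:
    """Complete a replicate vector to ``target_count`` values.

    Missing entries (NaN, or slots beyond the given length) are filled with
    independent draws from N(mean, sd^2) of the observed values (sample sd,
    n-1 denominator).  Observed values are untouched.
    """
    values = np.asarray(values, dtype=float)
    observed = values[np.isfinite(values)]
    if observed.size < 2:
        raise ImputationError(
            f"need >= 2 observed replicate values, got {observed.size}")
    out = np.full(target_count, np.nan)
    out[: values.size] = values
    missing = ~np.isfinite(out)
    if not missing.any():
        return values.copy()
    mu = float(observed.mean())
    sd = float(observed.std(ddof=1))
    out[missing] = rng.normal(mu, sd, size=int(missing.sum()))
    return out


def impute_matrix(matrix: pd.DataFrame, sheet: pd.DataFrame, seed: int = 0):
    """Fill missing values in an expression matrix, replicate-group-wise.

    Samples are grouped by (cell_line, dose, time); within a group each probe's
    missing replicate values are imputed from the observed ones.  Probes with
    fewer than two observed values in some group are left untouched and
    returned as ``flagged``.
    """
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    flagged = set()
    for _, grp in sheet.groupby(["cell_line", "dose_uM", "time_h"], sort=True):
        cols = [c for c in grp["sample_id"] if c in out.columns]
        block = out[cols].to_numpy(dtype=float)
        nan_rows = np.where(np.isnan(block).any(axis=1))[0]
        for i in nan_rows:
            try:
                out.loc[out.index[i], cols] = impute_missing_replicate(
                    block[i], len(cols), rng)
            except ImputationError:
                flagged.add(out.index[i])
    if flagged:
        logger.warning("imputation refused for %d probe(s): fewer than 2 "
                       "observed replicates in some group", len(flagged))
    return out, sorted(flagged)


# ---------------------------------------------------------------------------
# the screen
# ---------------------------------------------------------------------------

def run_marker_screen(matrix: pd.DataFrame, design: StudyDesign,
                      fdr_level: float = 0.05,
                      prior: PriorConfig = PriorConfig(),
                      optimizer: OptimizerSettings = OptimizerSettings(),
                      seed: int = 0) -> list[MarkerCall]:
    """Run the five-test screen on every probe of the matrix.

    The matrix is imputed up front with ``seed``; probes whose GP fit fails in
    any test are excluded from the calls (with a logged entry) rather than
    silently dropped from FDR cohorts.
    """
    matrix, flagged = impute_matrix(matrix, design.sheet, seed=seed)
    if flagged:
        matrix = matrix.drop(index=flagged)
    role_series = {role: design.replicate_series(role) for role in ROLE_NAMES}
    for role, series in role_series.items():
        if not series:
            raise ValueError(f"study design has no samples for role {role!r}")

    probes = list(matrix.index)
    p_matrix = np.ones((len(probes), 5))
    failed = set()
    for gi, probe in enumerate(probes):
        row = matrix.loc[probe]

        def tcs(role):
            reps = [(grid, row[ids].to_numpy(dtype=float))
                    for grid, ids in role_series[role]]
            return TimeCourseSet(gene_id=str(probe), replicates=reps,
                                 condition_label=role)

        for ti, (role_a, role_b) in enumerate(TEST_CONTRASTS):
            try:
                res = lr_test(tcs(role_a), tcs(role_b), prior=prior,
                              optimizer=optimizer)
                p_matrix[gi, ti] = res.p_value
            except Exception as exc:
                logger.warning("marker screen: probe %s failed test %d (%s)",
                               probe, ti + 1, exc)
                failed.add(probe)
    keep = [i for i, probe in enumerate(probes) if probe not in failed]
    if failed:
        logger.warning("marker screen: %d probe(s) excluded after fit "
                       "failures: %s", len(failed), sorted(failed))

    q_matrix = np.ones_like(p_matrix)
    passed = np.zeros_like(p_matrix, dtype=bool)
    for ti in range(5):
        q, sel = bh_adjust(p_matrix[keep, ti], fdr_level)
        q_matrix[keep, ti] = q
        passed[keep, ti] = sel

    calls = []
    for i in keep:
        calls.append(MarkerCall(
            probe_id=str(probes[i]),
            p_values=p_matrix[i].copy(),
            q_values=q_matrix[i].copy(),
            passed=passed[i].copy(),
            selected=combine_selection(passed[i]),
        ))
    return calls


def calls_to_frame(calls: list[MarkerCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {"probe_id": c.probe_id}
        for t in range(5):
            row[f"p_test{t + 1}"] = c.p_values[t]
            row[f"q_test{t + 1}"] = c.q_values[t]
            row[f"passed_test{t + 1}"] = bool(c.passed[t])
        row["selected"] = c.selected
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixture generation: a ragged study with engineered ground truth
# ---------------------------------------------------------------------------

#: engineered probe classes and the tests (1-5) in which they are truly DE
FIXTURE_CLASSES = {
    "marker": (1, 2, 3),          # the target phenotype: selected
    "null": (),                   # no signal anywhere
    "group_only": (1,),           # baseline difference, no drug response
    "responds_everywhere": (2, 3, 4, 5),   # responds in both groups
    "marker_but_test4": (1, 2, 3, 4),      # disqualified by the last two tests
}

#: smoothing of the engineered mean profiles over the 0-24 h design (squared-
#: exponential kernel, so correlation ~0.5 at a 6 h lag)
FIXTURE_SMOOTHING = 50.0
#: amplitude of the engineered profiles relative to noise sd 0.2
FIXTURE_AMPLITUDE = 1.5


def make_table1_fixture(n_probes: int = 50, n_markers: int = 10, seed: int = 0,
                        noise_sd: float = 0.2, n_replicates: int = 4):
    """Synthetic ragged study with known marker truth.

    Returns ``(matrix, sheet, truth)``: an expression matrix over the study's
    ragged grids (control at 0/2/6/12/24 h, treated conditions at subsets),
    its sample sheet, and a per-probe truth table (class plus intended
    selection flag).  ``n_markers`` probes are true markers; the rest cycle
    through the decoy classes.
    """
    rng = np.random.default_rng(seed)
    union = np.array([0.0, 2.0, 6.0, 12.0, 24.0])
    lines = list(RESPONSIVE_LINES) + list(NONRESPONSIVE_LINES)

    records = []
    for line in lines:
        for level, dose in (("control", 0.0), ("low", 0.1), ("high", 1.0)):
            grid = DEFAULT_GRIDS[(line, level)]
            for rep in range(1, n_replicates + 1):
                for t in grid:
                    sid = f"{line}_{level}_r{rep}_t{t:g}"
                    records.append({"sample_id": sid, "cell_line": line,
                                    "treatment": "DMSO" if dose == 0 else "lapatinib",
                                    "dose_uM": dose, "time_h": float(t),
                                    "replicate": rep})
    sheet = pd.DataFrame(records)

    decoys = [c for c in FIXTURE_CLASSES if c != "marker"]
    classes = ["marker"] * n_markers + [
        decoys[i % len(decoys)] for i in range(n_probes - n_markers)]

    # role -> index into the per-probe set of latent profiles
    matrix_rows, truth_rows = [], []
    for pi, cls in enumerate(classes):
        de_tests = FIXTURE_CLASSES[cls]
        draw = lambda: FIXTURE_AMPLITUDE * sample_mean_function(
            union, FIXTURE_SMOOTHING, rng)
        resp_control = draw()
        nonresp_control = resp_control.copy() if 1 not in de_tests else draw()
        profiles = {
            "responsive_control": resp_control,
            "responsive_low": draw() if 2 in de_tests else resp_control.copy(),
            "responsive_high": draw() if 3 in de_tests else resp_control.copy(),
            "nonresponsive_control": nonresp_control,
            "nonresponsive_low": draw() if 4 in de_tests else nonresp_control.copy(),
            "nonresponsive_high": draw() if 5 in de_tests else nonresp_control.copy(),
        }
        row = {}
        for rec in records:
            line, dose, t = rec["cell_line"], rec["dose_uM"], rec["time_h"]
            group = "responsive" if line in RESPONSIVE_LINES else "nonresponsive"
            role = f"{group}_{_dose_level(dose)}"
            k = int(np.searchsorted(union, t))
            row[rec["sample_id"]] = profiles[role][k] + rng.normal(scale=noise_sd)
        matrix_rows.append(row)
        truth_rows.append({"probe_id": f"p{pi:04d}", "class": cls,
                           "is_marker": cls == "marker"})

    matrix = pd.DataFrame(matrix_rows,
                          index=pd.Index([r["probe_id"] for r in truth_rows],
                                         name="probe_id"))
    truth = pd.DataFrame(truth_rows)
    return matrix, sheet, truth
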