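"""Cross-validated subject classification and parameter stability.

For every model and subject, the model is fit to the mean of a random
training subset of trials and evaluated on the 10 held-out test trials;
10 such iterations per subject.  Three summaries come out:

* an out-of-sample combined cAIC per model (mean test-trial MSE, with
  effective degrees of freedom summed over test trials), averaged
  across subjects;
* classification scores from the tensor of RMSEs comparing every test
  mean trace against every fitted model trace.  The *overall* score is
  the probability that the correct subject beats every competitor, the
  *pairwise* score the probability of beating one random competitor;
  ties count against the classifier (strict inequality);
* per-parameter ICCs across the 10 iterations, quantifying how stable
  the fitted parameters are for a given subject.

A model-free reference classifier replaces the fitted model trace by
the training-trial mean itself, bounding what any model could achieve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Trace
from .fitting import REDUCED_SWARM, FitResult, SwarmConfig, fit_model
from .models import get_model, simulate
from .selection import combined_crossval_caic, effective_df, icc
from .synth import StudyDesign

__all__ = [
    "CrossvalSplit",
    "CrossvalReport",
    "make_splits",
    "classification_scores",
    "run_crossval",
]


@dataclass(frozen=True)
class CrossvalSplit:
    subject: str
    iteration: int
    test_ids: tuple[int, ...]
    train_ids: tuple[int, ...]


def make_splits(
    trial_ids: dict[str, list[int]],
    n_iter: int = 10,
    n_test: int = 10,
    rng: np.random.Generator | None = None,
) -> list[CrossvalSplit]:
    """Random train/test partitions per subject, ``n_test`` held out."""
    rng = rng or np.random.default_rng()
    splits = []
    for subject, ids in trial_ids.items():
        ids = list(ids)
        if len(ids) <= n_test:
            raise ValueError(
                f"subject {subject} has {len(ids)} trials; needs > {n_test}"
            )
        for it in range(n_iter):
            test = sorted(rng.choice(ids, size=n_test, replace=False).tolist())
            train = sorted(set(ids) - set(test))
            splits.append(CrossvalSplit(subject, it, tuple(test), tuple(train)))
    return splits


def classification_scores(tensor: np.ndarray) -> tuple[float, float]:
    """Overall and pairwise subject-identification scores, in percent.

    ``tensor[i, m, j, n]`` is the RMSE between the mean test trace of
    iteration i, subject m and the fitted model trace from training
    iteration j, subject n.  For each test (i, m) and competitor n != m
    the fraction over j of strict wins RMSE[i,m,i,m] < RMSE[i,m,j,n] is
    formed; the overall score multiplies the fractions across
    competitors, the pairwise score averages them.
    """
    t = np.asarray(tensor, dtype=float)
    if t.ndim != 4 or t.shape[0] != t.shape[2] or t.shape[1] != t.shape[3]:
        raise ValueError("tensor must have shape (iters, subjects, iters, subjects)")
    if not np.all(np.isfinite(t)):
        raise ValueError("tensor has missing entries")
    n_iter, n_subj = t.shape[:2]
    self_rmse = t[np.arange(n_iter)[:, None], np.arange(n_subj)[None, :],
                  np.arange(n_iter)[:, None], np.arange(n_subj)[None, :]]
    wins = self_rmse[:, :, None, None] < t            # (i, m, j, n)
    frac = wins.mean(axis=2)                          # (i, m, n)
    competitor = ~np.eye(n_subj, dtype=bool)          # n != m
    prod = np.where(competitor[None, :, :], frac, 1.0).prod(axis=2)
    p_overall = float(prod.mean() * 100.0)
    p_pairwise = float(frac[:, competitor].mean() * 100.0)
    return p_overall, p_pairwise


@dataclass
class CrossvalReport:
    """All cross-validation outputs for a set of models on one dataset."""

    models: list[str]
    caic: dict[str, float]                       # combined cAIC, subject-averaged
    overall: dict[str, float]                    # % classification scores
    pairwise: dict[str, float]
    param_means: dict[str, dict[str, float]]     # model -> parameter -> mean
    param_icc: dict[str, dict[str, float]]       # model -> parameter -> ICC
    baseline_overall: float                      # model-free training-mean classifier
    baseline_pairwise: float
    seed: int
    fits: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "models": self.models,
            "caic": self.caic,
            "overall": self.overall,
            "pairwise": self.pairwise,
            "param_means": self.param_means,
            "param_icc": self.param_icc,
            "baseline_overall": self.baseline_overall,
            "baseline_pairwise": self.baseline_pairwise,
            "seed": self.seed,
        }

    def score_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "model": self.models,
                "caic": [self.caic[m] for m in self.models],
                "overall_pct": [self.overall[m] for m in self.models],
                "pairwise_pct": [self.pairwise[m] for m in self.models],
            }
        )

    def param_table(self):
        """Per-model parameter means and ICCs as a long-format DataFrame."""
        import pandas as pd

        rows = [
            {"model": m, "parameter": p,
             "mean": self.param_means[m][p], "icc": self.param_icc[m][p]}
            for m in self.models
            for p in self.param_means[m]
        ]
        return pd.DataFrame(rows)


def run_crossval(
    models: list[str],
    dataset: dict[str, list[Trace]],
    design: StudyDesign,
    config: SwarmConfig = REDUCED_SWARM,
    seed: int = 0,
    n_iter: int = 10,
    n_test: int = 10,
) -> CrossvalReport:
    """Full cross-validated classification/stability pipeline.

    ``dataset`` maps subject ids to preprocessed per-trial deviation
    traces on the design's parse grid (downshift sign convention).
    Identical training means (e.g. noiseless cohorts) share one cached
    fit, so repeated iterations cannot introduce spurious within-subject
    parameter variance.
    """
    rng = np.random.default_rng(seed)
    grid = design.parse_grid
    pert = design.perturbation(-1)
    i0 = grid.onset_index
    subjects = sorted(dataset)
    trial_ids = {s: list(range(len(dataset[s]))) for s in subjects}
    splits = make_splits(trial_ids, n_iter=n_iter, n_test=n_test, rng=rng)
    by_key = {(s.subject, s.iteration): s for s in splits}

    # Mean traces per (subject, iteration)
    def mean_trace(subject: str, ids: tuple[int, ...]) -> Trace:
        return Trace(grid=grid,
                     values=np.mean([dataset[subject][i].values for i in ids], axis=0))

    test_means = {k: mean_trace(k[0], sp.test_ids) for k, sp in by_key.items()}
    train_means = {k: mean_trace(k[0], sp.train_ids) for k, sp in by_key.items()}

    # Per test trial: MSE uses the post-onset window; effective df comes
    # from that trial's own baseline samples.  A flat (noise-free)
    # baseline carries no autocorrelation evidence: treat the window as
    # fully independent samples.
    n_post = grid.n_samples - i0

    def _trial_df(tr: Trace) -> float:
        try:
            return effective_df([tr.baseline], n_post)
        except ValueError:
            return float(n_post)

    trial_dfs = {s: [_trial_df(tr) for tr in dataset[s]] for s in subjects}

    report = CrossvalReport(
        models=list(models), caic={}, overall={}, pairwise={},
        param_means={}, param_icc={}, baseline_overall=0.0,
        baseline_pairwise=0.0, seed=seed,
    )

    def rmse_tensor(model_traces: dict) -> np.ndarray:
        t = np.empty((n_iter, len(subjects), n_iter, len(subjects)))
        for i in range(n_iter):
            for m, subj_m in enumerate(subjects):
                test = test_means[(subj_m, i)].values[i0:]
                for j in range(n_iter):
                    for n, subj_n in enumerate(subjects):
                        ref = model_traces[(subj_n, j)][i0:]
                        t[i, m, j, n] = np.sqrt(np.mean((test - ref) ** 2))
        return t

    fit_cache: dict[tuple, FitResult] = {}
    for model_name in models:
        spec = get_model(model_name)
        model_traces: dict[tuple, np.ndarray] = {}
        fit_results: dict[tuple, FitResult] = {}
        for key, train in train_means.items():
            subj, it = key
            fit_seed = seed + 7919 * (1 + models.index(model_name))
            cache_key = (model_name, train.values.tobytes(), fit_seed)
            if cache_key not in fit_cache:
                cfg = SwarmConfig(**{**config.__dict__, "seed": fit_seed + it})
                fit_cache[cache_key] = fit_model(spec, train, pert, grid, cfg)
            fit = fit_cache[cache_key]
            fit_results[key] = fit
            model_traces[key] = simulate(spec, fit.params, pert, grid).values

        # combined out-of-sample cAIC, averaged across subjects
        subj_caic = []
        for subj in subjects:
            mses, dfs = [], []
            for it in range(n_iter):
                sp = by_key[(subj, it)]
                ref = model_traces[(subj, it)][i0:]
                for tid in sp.test_ids:
                    resid = dataset[subj][tid].values[i0:] - ref
                    # exact-zero residuals (possible only for noise-free
                    # synthetic trials) are floored so ln(MSE) stays finite
                    mses.append(max(float(np.mean(resid**2)), np.finfo(float).tiny))
                    dfs.append(trial_dfs[subj][tid])
            subj_caic.append(combined_crossval_caic(mses, dfs, n_test, spec.n_free))
        report.caic[model_name] = float(np.mean(subj_caic))

        p_overall, p_pairwise = classification_scores(rmse_tensor(model_traces))
        report.overall[model_name] = p_overall
        report.pairwise[model_name] = p_pairwise

        # parameter stability across iterations
        means, iccs = {}, {}
        for p_idx, pname in enumerate(spec.free_params):
            table = np.array(
                [[fit_results[(subj, it)].params.as_dict()[pname]
                  for it in range(n_iter)] for subj in subjects]
            )
            means[pname] = float(table.mean())
            try:
                iccs[pname] = float(icc(table).icc)
            except ValueError:  # zero variance everywhere: undefined
                iccs[pname] = float("nan")
        report.param_means[model_name] = means
        report.param_icc[model_name] = iccs
        report.fits[model_name] = fit_results

    # model-free reference: classify against training means directly
    naive_traces = {k: v.values for k, v in train_means.items()}
    report.baseline_overall, report.baseline_pairwise = classification_scores(
        rmse_tensor(naive_traces)
    )
    return report
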