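"""Permutation test for group differences in group-level mixture parameters.

With modest trial counts per subject, subject-level fits of the mixture are
noisy; a robust alternative is to fit the model to the pooled trials of
each group and ask whether the two group-level parameter estimates differ
more than expected by chance.  Chance is generated by shuffling *subject*
group labels (trials travel with their subject — trials within a subject
are not exchangeable), preserving the original group sizes, and refitting
per shuffled group.

For each parameter (retrieval success p_t and concentration K) the result
records the observed difference (group2 - group1, labels in sorted order),
the permutation distribution, a two-tailed p-value with add-one correction

    p = ( #{ |perm diff| >= |observed diff| } + 1 ) / (B + 1)

(never exactly 0, ties counted as exceedances), and a z-score of the
observed difference against the permutation distribution's mean and SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mixture import ErrorSample, FitConfig, FitResult, fit_mixture_mle

__all__ = ["PermutationResult", "permutation_group_test"]


@dataclass(frozen=True)
class PermutationResult:
    groups: tuple[str, str]
    observed: dict[str, float]  # parameter -> observed group2 - group1
    permuted: dict[str, np.ndarray]  # parameter -> B permuted differences
    p_value: dict[str, float]
    z_score: dict[str, float]
    group_fits: tuple[FitResult, FitResult]
    n_iterations: int
    seed: int | None
    n_failed: int = 0


def _pooled_fit(samples: list[np.ndarray], cfg: FitConfig) -> FitResult:
    pooled = ErrorSample(np.concatenate(samples))
    return fit_mixture_mle(pooled, cfg)


def permutation_group_test(
    samples: list[ErrorSample],
    B: int = 1000,
    seed: int | None = None,
    fit_config: FitConfig | None = None,
    max_failure_rate: float = 0.05,
) -> PermutationResult:
    """Two-group permutation test on pooled-fit mixture parameters.

    ``samples`` holds one ErrorSample per subject with ``label`` giving the
    group.  Exactly two distinct labels are required.  Observed fits use
    the full multi-start configuration; permutation refits warm-start from
    the all-trials pooled estimate (the permuted groups are mixtures of the
    original ones, so the pooled parameters are an excellent neighbourhood),
    with one generic fallback start.  Aborts if more than
    ``max_failure_rate`` of the permutation fits fail to converge.
    """
    labels = sorted({s.label for s in samples})
    if len(labels) != 2:
        raise ValueError(f"exactly two group labels required, got {labels!r}")
    cfg = fit_config or FitConfig()
    by_subject = [np.asarray(s.errors, dtype=float) for s in samples]
    group_idx = np.array([labels.index(s.label) for s in samples])
    n_g2 = int(group_idx.sum())
    if n_g2 == 0 or n_g2 == len(samples):
        raise ValueError("each group needs at least one subject")

    fit1 = _pooled_fit([e for e, g in zip(by_subject, group_idx) if g == 0], cfg)
    fit2 = _pooled_fit([e for e, g in zip(by_subject, group_idx) if g == 1], cfg)
    observed = {
        "p_t": fit2.params.p_t - fit1.params.p_t,
        "kappa": fit2.params.kappa - fit1.params.kappa,
    }

    pooled_all = fit_mixture_mle(ErrorSample(np.concatenate(by_subject)), cfg)
    warm = FitConfig(
        min_trials=cfg.min_trials,
        start_p=(pooled_all.params.p_t, 0.5),
        start_kappa=(pooled_all.params.kappa, 8.0),
        kappa_min=cfg.kappa_min,
        kappa_max=cfg.kappa_max,
        tol=max(cfg.tol, 1e-7),
        max_iter=cfg.max_iter,
        polish=False,
    )

    rng = np.random.default_rng(seed)
    perm = {"p_t": np.empty(B), "kappa": np.empty(B)}
    n_failed = 0
    idx = np.arange(len(samples))
    for b in range(B):
        shuffled = rng.permutation(idx)
        g2 = np.zeros(len(samples), dtype=bool)
        g2[shuffled[:n_g2]] = True
        f2 = _pooled_fit([by_subject[i] for i in idx[g2]], warm)
        f1 = _pooled_fit([by_subject[i] for i in idx[~g2]], warm)
        if not (f1.converged and f2.converged):
            n_failed += 1
        perm["p_t"][b] = f2.params.p_t - f1.params.p_t
        perm["kappa"][b] = f2.params.kappa - f1.params.kappa
    if n_failed > max_failure_rate * B:
        raise RuntimeError(
            f"{n_failed}/{B} permutation fits failed to converge "
            f"(> {max_failure_rate:.0%}); group-level fits are unstable"
        )

    p_value, z_score = {}, {}
    for key in ("p_t", "kappa"):
        exceed = int(np.sum(np.abs(perm[key]) >= abs(observed[key])))
        p_value[key] = (exceed + 1) / (B + 1)
        sd = float(np.std(perm[key], ddof=1))
        z_score[key] = (observed[key] - float(np.mean(perm[key]))) / sd if sd > 0 else float("nan")

    return PermutationResult(
        groups=(labels[0], labels[1]),
        observed=observed,
        permuted=perm,
        p_value=p_value,
        z_score=z_score,
        group_fits=(fit1, fit2),
        n_iterations=B,
        seed=seed,
        n_failed=n_failed,
    )
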