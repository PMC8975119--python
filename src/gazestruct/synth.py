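"""Synthetic image catalogs and simulated gaze datasets.

The generator produces the full study scaffolding without any external
data: 27 textured grayscale images (9 per category, pictorial-depth
classes balanced within category), rated-property scores, symmetric
child/adult dissimilarity matrices, 5 target patches per image, and
simulated 500 Hz gaze streams whose hit/latency/fixation-duration
structure follows known generative parameters so that the whole analysis
chain can be validated by parameter recovery.

Textures are phase-randomized 1/f^alpha fields whose luminance histogram
is rank-remapped onto a beta-family distribution solved to hit target
entropy (bits) and skew; the three categories occupy distinct property
regimes so that category structure is real, not just labelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .image import GrayImage
from .design import ExperimentDesign
from .gaze import GazeTrial, SAMPLE_PERIOD_MS
from .stimgen import Catalog, RatedProperties, sample_patches, ring_locations, CATEGORIES

__all__ = [
    "synth_spectral_field",
    "solve_beta_histogram",
    "synth_texture",
    "synth_catalog",
    "EffectSpec",
    "SimOutput",
    "simulate_dataset",
    "simulate_success_table",
    "simulate_latency_table",
    "recovery_report",
]


def synth_spectral_field(alpha: float, size: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Phase-randomized Gaussian field with power spectrum ∝ f^-alpha.

    Returns a float array (zero mean, unit variance).  The amplitude
    filter is f^(-alpha/2) with radial frequency in cycles/image of the
    shorter axis; the DC component is zero.
    """
    h, w = size
    noise = rng.standard_normal((h, w))
    spec = np.fft.fft2(noise)
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    s = min(h, w)
    f = s * np.sqrt(fy**2 + fx**2)
    amp = np.zeros_like(f)
    nz = f > 0
    amp[nz] = f[nz] ** (-alpha / 2.0)
    out = np.real(np.fft.ifft2(spec * amp))
    out -= out.mean()
    sd = out.std()
    return out / sd if sd > 0 else out


def _beta_discrete_stats(a: float, b: float, n_levels: int = 256) -> tuple[float, float]:
    """Entropy (bits) and skew of a beta distribution quantized to n levels."""
    edges = np.linspace(0.0, 1.0, n_levels + 1)
    p = np.diff(stats.beta.cdf(edges, a, b))
    p = np.clip(p, 0, None)
    tot = p.sum()
    if tot <= 0:
        return 0.0, 0.0
    p = p / tot
    nzp = p[p > 0]
    ent = float(-(nzp * np.log2(nzp)).sum())
    k = np.arange(n_levels, dtype=float)
    m = (p * k).sum()
    v = (p * (k - m) ** 2).sum()
    sk = 0.0 if v == 0 else float((p * (k - m) ** 3).sum() / v**1.5)
    return ent, sk


def solve_beta_histogram(
    entropy_target: float, skew_target: float, n_levels: int = 256, tol: float = 0.08
) -> tuple[float, float]:
    """Find beta(a, b) whose quantized histogram hits entropy and skew targets.

    Raises when no member of the beta family comes close enough (the
    feasible skew range shrinks as entropy approaches its 8-bit maximum).
    """
    if not (0.0 < entropy_target <= np.log2(n_levels)):
        raise ValueError(f"entropy target must lie in (0, {np.log2(n_levels):.0f}] bits")

    def err(logab):
        a, b = np.exp(logab)
        ent, sk = _beta_discrete_stats(a, b, n_levels)
        return [ent - entropy_target, sk - skew_target]

    best = None
    for x0 in ([0.0, 0.0], [1.0, 1.0], [-0.5, 0.5], [0.5, -0.5], [1.5, 0.0]):
        try:
            sol = optimize.least_squares(err, x0, bounds=(-4, 6))
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.cost < 1e-10:
            break
    if best is None or np.sqrt(2 * best.cost) > tol:
        raise ValueError(
            f"infeasible (entropy={entropy_target}, skew={skew_target}) pair "
            "for the beta histogram family"
        )
    a, b = np.exp(best.x)
    return float(a), float(b)


def synth_texture(
    alpha_target: float,
    entropy_target: float,
    skew_target: float,
    size: tuple[int, int] = (256, 256),
    seed: int | np.random.Generator = 0,
) -> GrayImage:
    """Texture with controlled spectral slope, histogram entropy and skew.

    A 1/f^alpha field is rank-remapped onto the solved beta histogram:
    each pixel's rank is assigned the gray level whose cumulative target
    count it falls into, which reproduces the target histogram exactly up
    to rounding while approximately preserving the spectral slope
    (monotone transforms of a Gaussian field retain its correlation
    structure to first order).
    """
    if not (0.0 <= alpha_target <= 3.0):
        raise ValueError("alpha target must lie in [0, 3]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a, b = solve_beta_histogram(entropy_target, skew_target)
    field = synth_spectral_field(alpha_target, size, rng)
    n = field.size
    edges = np.linspace(0.0, 1.0, 257)
    p = np.diff(stats.beta.cdf(edges, a, b))
    p = p / p.sum()
    counts = np.floor(p * n).astype(int)
    remainder = n - counts.sum()
    frac = p * n - np.floor(p * n)
    counts[np.argsort(-frac)[:remainder]] += 1
    levels_sorted = np.repeat(np.arange(256, dtype=np.uint8), counts)
    order = np.argsort(field.ravel(), kind="stable")
    out = np.empty(n, dtype=np.uint8)
    out[order] = levels_sorted
    return GrayImage(out.reshape(size))


# property regimes per category: (alpha, entropy bits, skew) means
_CATEGORY_REGIMES = {
    "vegetation": (1.0, 7.1, 0.2),
    "natural_element": (1.9, 6.3, 0.7),
    "artifact": (1.45, 7.5, -0.35),
}


def synth_catalog(
    seed: int = 0,
    n_per_category: int = 9,
    size: tuple[int, int] = (1024, 1280),
    patch_diameter: int = 235,
) -> Catalog:
    """Generate the 27-image catalog with labels, ratings and dissimilarities.

    Depth classes are balanced 5/4 within each category and drive the
    rated-depth score; the remaining ratings carry mild category structure
    plus noise.  Dissimilarities are scaled property-space distances with
    independent noise for the child and adult variants (children noisier).
    """
    rng = np.random.default_rng(seed)
    images: dict[str, GrayImage] = {}
    categories: dict[str, str] = {}
    depth_classes: dict[str, str] = {}
    rated: dict[str, RatedProperties] = {}
    props = {}

    for cat in CATEGORIES:
        a0, e0, s0 = _CATEGORY_REGIMES[cat]
        n_high = (n_per_category + 1) // 2
        depth_seq = ["high"] * n_high + ["low"] * (n_per_category - n_high)
        for i in range(n_per_category):
            img_id = f"{cat[:3]}{i:02d}"
            alpha_t = float(np.clip(a0 + rng.normal(0, 0.08), 0.2, 2.8))
            ent_t = float(np.clip(e0 + rng.normal(0, 0.08), 4.0, 7.9))
            skew_t = float(np.clip(s0 + rng.normal(0, 0.08), -1.2, 1.2))
            images[img_id] = synth_texture(alpha_t, ent_t, skew_t, size, rng)
            categories[img_id] = cat
            depth_classes[img_id] = depth_seq[i]
            depth_score = (0.8 if depth_seq[i] == "high" else -0.8) + rng.normal(0, 0.3)
            rated[img_id] = RatedProperties(
                curvature=float(rng.normal(0.5 if cat == "vegetation" else -0.2, 0.6)),
                regularity=float(rng.normal(0.6 if cat == "artifact" else -0.3, 0.6)),
                symmetry=float(rng.normal(0, 0.7)),
                depth=float(depth_score),
            )
            props[img_id] = np.array([alpha_t, ent_t, skew_t, depth_score])

    ids = list(images)
    P = np.vstack([props[i] for i in ids])
    P = (P - P.mean(0)) / P.std(0)

    def dissim(cols, scale_noise, weights=None):
        sub = P[:, cols] * (np.asarray(weights) if weights is not None else 1.0)
        D = np.sqrt(((sub[:, None, :] - sub[None, :, :]) ** 2).sum(-1))
        D = D / D.max()
        noise = rng.normal(0, scale_noise, D.shape)
        noise = (noise + noise.T) / 2.0
        M = np.clip(D + noise, 0, None)
        np.fill_diagonal(M, 0.0)
        return pd.DataFrame(M, index=ids, columns=ids)

    # children's similarity judgments lean on lower-level statistics and are
    # noisier; adults weight the higher-level (depth) dimension heavily
    child = dissim([0, 1, 2], 0.30)
    adult = dissim([0, 1, 2, 3], 0.08, weights=[1.0, 1.0, 1.0, 2.5])

    patches = {
        img_id: sample_patches(img, img_id, n=5, diameter=patch_diameter, seed=rng)
        for img_id, img in images.items()
    }
    return Catalog(
        images=images,
        categories=categories,
        depth_classes=depth_classes,
        rated=rated,
        child_dissimilarity=child,
        adult_dissimilarity=adult,
        patches=patches,
    )


@dataclass
class EffectSpec:
    """Generative parameters of the behavioral simulator.

    Success is Bernoulli with a logistic model over standardized
    predictors plus crossed random intercepts; hit latency is log-normal
    around a linear mean structure (ms) and truncation at the timeout
    converts late hits to misses, mimicking censoring.  Behavioral
    parameters shape the emitted 500 Hz sample streams.  Defaults follow
    the infant group's observed marginals (hit rate ~ .39, median hit
    latency ~ 1.47 s, mean fixation duration ~ 467 ms).
    """

    success_intercept: float = float(special.logit(0.39))
    success_coefs: dict[str, float] = field(default_factory=dict)
    success_re_sd: dict[str, float] = field(
        default_factory=lambda: {"participant_id": 0.5, "background_id": 0.3, "location_idx": 0.2}
    )
    # median of the log-normal draw is intercept * exp(-sigma_log^2 / 2);
    # 1520 ms puts the simulated median hit latency near the infant group's
    # observed ~1.47 s
    latency_intercept: float = 1520.0
    latency_coefs: dict[str, float] = field(default_factory=dict)
    latency_re_sd: dict[str, float] = field(
        default_factory=lambda: {"participant_id": 150.0, "background_id": 80.0}
    )
    latency_resid_sd: float = 350.0
    mean_fix_duration: float = 467.0
    dropout_prob: float = 0.10
    head_drift_sd: float = 0.6
    timeout_ms: float = 4500.0
    dwell_ms: float = 100.0

    @classmethod
    def infant(cls, **overrides) -> "EffectSpec":
        return cls(**overrides)

    @classmethod
    def adult(cls, **overrides) -> "EffectSpec":
        base = dict(
            success_intercept=float(special.logit(0.98)),
            latency_intercept=650.0,
            latency_resid_sd=150.0,
            mean_fix_duration=230.0,
            dropout_prob=0.01,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class SimOutput:
    trials: list[GazeTrial]
    truth: pd.DataFrame
    effects: EffectSpec
    seed: int


def _standardized_predictors(design_trials: pd.DataFrame, names) -> pd.DataFrame:
    out = {}
    for name in names:
        if name not in design_trials.columns:
            raise KeyError(f"design lacks predictor {name}")
        col = design_trials[name]
        if col.dtype == object:
            col = (col == "congruent").astype(float)
        col = col.astype(float)
        sd = col.std(ddof=0)
        out[name] = (col - col.mean()) / (sd if sd > 0 else 1.0)
    return pd.DataFrame(out, index=design_trials.index)


def simulate_dataset(
    design: ExperimentDesign,
    effects: EffectSpec,
    n_participants: int = 39,
    group: str = "infant",
    seed: int = 0,
    ring=None,
    width: int = 1280,
    height: int = 1024,
    target_radius: float = 117.5,
    runs_per_participant: int = 1,
) -> SimOutput:
    """Simulate raw gaze streams for every participant x trial.

    Each participant is assigned an experiment version cyclically (adults
    may run two versions).  Per trial the hit outcome and latency are
    drawn from the effect spec, then a 500 Hz sample stream realizing the
    outcome is emitted: a center start, fixations jumping between AOIs
    (samples during saccades are dropped as the tracker would), a final
    >= 100 ms target dwell at the drawn latency for hits, random dropout
    blocks (never inside the qualifying dwell), and a random-walk head
    distance.
    """
    rng = np.random.default_rng(seed)
    if ring is None:
        ring = ring_locations(width, height)
    pred_names = sorted(set(effects.success_coefs) | set(effects.latency_coefs))
    Xs = _standardized_predictors(design.trials, pred_names) if pred_names else None

    u_bg = {b: rng.normal(0, effects.success_re_sd.get("background_id", 0.0))
            for b in design.trials["background_id"].unique()}
    u_loc = {l: rng.normal(0, effects.success_re_sd.get("location_idx", 0.0))
             for l in design.trials["location_idx"].unique()}
    v_bg = {b: rng.normal(0, effects.latency_re_sd.get("background_id", 0.0))
            for b in design.trials["background_id"].unique()}

    gaze_trials: list[GazeTrial] = []
    truth_rows = []
    for p in range(n_participants):
        pid = f"{group[:3]}{p:03d}"
        u_p = rng.normal(0, effects.success_re_sd.get("participant_id", 0.0))
        v_p = rng.normal(0, effects.latency_re_sd.get("participant_id", 0.0))
        for run in range(1, runs_per_participant + 1):
            version = (p * runs_per_participant + run - 1) % design.n_versions + 1
            vtrials = design.version(version)
            for _, row in vtrials.iterrows():
                eta = effects.success_intercept + u_p + u_bg[row["background_id"]] + u_loc[row["location_idx"]]
                mlat = effects.latency_intercept + v_p + v_bg[row["background_id"]]
                if Xs is not None:
                    x = Xs.loc[row.name]
                    eta += sum(effects.success_coefs.get(nm, 0.0) * x[nm] for nm in pred_names)
                    mlat += sum(effects.latency_coefs.get(nm, 0.0) * x[nm] for nm in pred_names)
                hit = rng.random() < special.expit(eta)
                latency = None
                truncated = False
                if hit:
                    m = max(mlat, 250.0)
                    cv = effects.latency_resid_sd / effects.latency_intercept
                    sigma = np.sqrt(np.log(1 + cv**2))
                    latency = float(m * np.exp(rng.normal(-sigma**2 / 2.0, sigma)))
                    latency = 2.0 * round(latency / 2.0)
                    if latency >= effects.timeout_ms - effects.dwell_ms - 100.0:
                        hit, latency, truncated = False, None, True
                tid = f"{pid}_v{version}_t{int(row['trial_order']):02d}_r{run}"
                trial = _emit_trial(
                    tid, pid, hit, latency, int(row["location_idx"]), ring, effects, rng,
                )
                gaze_trials.append(trial)
                truth_rows.append(
                    {
                        "trial_id": tid,
                        "participant_id": pid,
                        "version": version,
                        "run": run,
                        "trial_order": int(row["trial_order"]),
                        "design_index": row.name,
                        "true_hit": hit,
                        "true_latency": latency,
                        "truncated": truncated,
                        "location_idx": int(row["location_idx"]),
                        "background_id": row["background_id"],
                    }
                )
    return SimOutput(gaze_trials, pd.DataFrame(truth_rows), effects, seed)


def _emit_trial(tid, pid, hit, latency, target_loc, ring, effects: EffectSpec, rng) -> GazeTrial:
    """Emit one 500 Hz sample stream realizing the drawn outcome."""
    dt = SAMPLE_PERIOD_MS
    center = ring.center
    positions = ring.positions
    n_loc = len(positions)
    non_target = [i for i in range(n_loc) if i != target_loc]
    saccade_ms = 30.0

    # fixation schedule: (start, duration, x, y, protected)
    sched = []
    t = 0.0
    end_t = latency if hit else effects.timeout_ms
    first = True
    while t < end_t - 1e-9:
        if first:
            x, y = center
            first = False
        else:
            loc = non_target[rng.integers(len(non_target))]
            x, y = positions[loc]
        dur = float(rng.gamma(4.0, effects.mean_fix_duration / 4.0))
        dur = max(80.0, dur)
        if t + dur + saccade_ms >= end_t:
            dur = max(40.0, end_t - t - saccade_ms)
            sched.append([t, dur, x, y, False])
            t = end_t
            break
        sched.append([t, dur, x, y, False])
        t += dur + saccade_ms
    if hit:
        dwell = max(effects.dwell_ms + 60.0, float(rng.gamma(4.0, effects.mean_fix_duration / 4.0)))
        tx, ty = positions[target_loc]
        sched.append([latency, dwell, tx, ty, True])
        total = latency + dwell
    else:
        total = effects.timeout_ms

    n = int(round(total / dt)) + 1
    tgrid = np.arange(n) * dt
    xs = np.full(n, np.nan)
    ys = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    protected = np.zeros(n, dtype=bool)
    for start, dur, x, y, prot in sched:
        i0 = int(np.ceil(start / dt))
        i1 = min(n - 1, int(np.floor((start + dur) / dt)))
        if i1 < i0:
            continue
        m = i1 - i0 + 1
        xs[i0 : i1 + 1] = x + rng.normal(0, 2.0, m)
        ys[i0 : i1 + 1] = y + rng.normal(0, 2.0, m)
        valid[i0 : i1 + 1] = True
        if prot:
            protected[i0 : i1 + 1] = True

    # dropout outside the protected dwell: tracking quality is bimodal --
    # most trials lose only a few percent, a minority (p = dropout_prob)
    # are poor-tracking trials losing roughly half their samples, which is
    # what the recorded-gaze inclusion rules are designed to catch
    if effects.dropout_prob > 0:
        if rng.random() < effects.dropout_prob:
            rate = rng.uniform(0.35, 0.65)
        else:
            rate = rng.uniform(0.01, 0.08)
        target_drop = rate * n
        dropped = 0
        for _ in range(80):
            if dropped >= target_drop:
                break
            blk = int(rng.integers(25, 150))  # 50-300 ms
            blk = min(blk, max(5, int(np.ceil(target_drop - dropped))))
            i0 = int(rng.integers(0, max(1, n - blk)))
            sl = slice(i0, i0 + blk)
            if protected[sl].any():
                continue
            dropped += valid[sl].sum()
            valid[sl] = False

    xs[~valid] = 0.0
    ys[~valid] = 0.0
    head = 600.0 + np.cumsum(rng.normal(0, effects.head_drift_sd, n))
    return GazeTrial(tid, pid, tgrid, xs, ys, valid, head)


def simulate_success_table(
    n_participants: int = 39,
    trials_per_participant: int = 36,
    coefs: dict[str, float] | None = None,
    re_sd: dict[str, float] | None = None,
    intercept: float = float(special.logit(0.39)),
    n_backgrounds: int = 27,
    n_locations: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Direct table-level simulation of the success GLMM (no gaze layer)."""
    rng = np.random.default_rng(seed)
    coefs = coefs or {}
    re_sd = re_sd or {"participant_id": 0.5, "background_id": 0.5, "location_idx": 0.5}
    n = n_participants * trials_per_participant
    df = pd.DataFrame(
        {
            "participant_id": np.repeat(np.arange(n_participants), trials_per_participant),
            "background_id": rng.integers(0, n_backgrounds, n),
            "location_idx": rng.integers(0, n_locations, n),
        }
    )
    eta = np.full(n, intercept)
    for g, sd in re_sd.items():
        u = rng.normal(0, sd, df[g].max() + 1)
        eta += u[df[g]]
    for name, b in coefs.items():
        df[name] = rng.standard_normal(n)
        eta += b * df[name]
    df["success"] = (rng.random(n) < special.expit(eta)).astype(float)
    return df


def simulate_latency_table(
    n_participants: int = 39,
    trials_per_participant: int = 14,
    coefs: dict[str, float] | None = None,
    re_sd: dict[str, float] | None = None,
    intercept: float = 1400.0,
    resid_sd: float = 350.0,
    n_backgrounds: int = 27,
    seed: int = 0,
) -> pd.DataFrame:
    """Direct table-level simulation of the latency LMM (hits only)."""
    rng = np.random.default_rng(seed)
    coefs = coefs or {}
    re_sd = re_sd or {"participant_id": 150.0, "background_id": 80.0}
    n = n_participants * trials_per_participant
    df = pd.DataFrame(
        {
            "participant_id": np.repeat(np.arange(n_participants), trials_per_participant),
            "background_id": rng.integers(0, n_backgrounds, n),
            "location_idx": rng.integers(0, 10, n),
        }
    )
    mu = np.full(n, float(intercept))
    for g, sd in re_sd.items():
        u = rng.normal(0, sd, df[g].max() + 1)
        mu += u[df[g]]
    for name, b in coefs.items():
        df[name] = rng.standard_normal(n)
        mu += b * df[name]
    df["latency"] = mu + rng.normal(0, resid_sd, n)
    df["success"] = 1.0
    return df


def recovery_report(
    design: ExperimentDesign,
    effects: EffectSpec,
    fit_terms: list[str],
    n_replicates: int = 20,
    n_participants: int = 39,
    seed: int = 0,
    dv: str = "success",
) -> pd.DataFrame:
    """Simulate -> analyze -> fit loop; reports recovery per coefficient.

    Each replicate simulates gaze for the full design, re-derives trial
    outcomes with the gaze module, assembles the model table, and fits the
    mixed model.  The report gives, per generative coefficient: mean
    estimate, bias, empirical SE, Wald-CI coverage of the true value, and
    the sign-recovery rate.
    """
    from . import pipeline  # local import to avoid a cycle

    true = effects.success_coefs if dv == "success" else effects.latency_coefs
    rows = {t: [] for t in fit_terms}
    covered = {t: 0 for t in fit_terms}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        sim = simulate_dataset(design, effects, n_participants=n_participants, seed=rep_seed)
        table = pipeline.analyze_simulation(sim, design)
        from .models import fit_success_glmm, fit_latency_lmm

        fit = (fit_success_glmm if dv == "success" else fit_latency_lmm)(table, fit_terms)
        for t in fit_terms:
            i = fit.terms.index(t)
            est, se = fit.params[i], fit.bse[i]
            rows[t].append(est)
            tv = true.get(t, 0.0)
            if est - 1.96 * se <= tv <= est + 1.96 * se:
                covered[t] += 1
    recs = []
    for t in fit_terms:
        ests = np.array(rows[t])
        tv = true.get(t, 0.0)
        recs.append(
            {
                "term": t,
                "true": tv,
                "mean_estimate": ests.mean(),
                "bias": ests.mean() - tv,
                "empirical_se": ests.std(ddof=1),
                "coverage": covered[t] / n_replicates,
                "sign_recovery": float(np.mean(np.sign(ests) == np.sign(tv))) if tv != 0 else np.nan,
                "n_replicates": n_replicates,
            }
        )
    return pd.DataFrame(recs)
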