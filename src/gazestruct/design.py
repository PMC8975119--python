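"""Balanced 8-version experiment builder and constraint auditor.

Each of the 8 versions holds 36 test trials drawn from the stimulus pool
under these restrictions (checked per version):

(i)   balance over target and background categories (3 categories in each
      role; counts may differ by at most 1);
(ii)  balance over the crossed 2x2 of category- and depth-congruency
      (cell counts within a configurable tolerance, default +-1);
(iii) no image appears more than twice as target or as background, and a
      repeated image's two occurrences differ in partner image, target
      location and hue.

The solver is a seeded greedy assignment with per-trial candidate
shuffling and bounded restarts; the constraint system is small and loose
enough that this terminates quickly on any reasonably diverse pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ExperimentDesign", "ConstraintReport", "build_design", "audit_design", "practice_trials"]


@dataclass
class ExperimentDesign:
    """Trials of all versions; ``trials`` has a ``version`` column (1-based)."""

    trials: pd.DataFrame
    n_versions: int
    trials_per_version: int
    congruency_tolerance: int = 1

    def version(self, v: int) -> pd.DataFrame:
        return self.trials[self.trials["version"] == v]


@dataclass
class ConstraintReport:
    balance_tables: dict
    violations: list[str]

    @property
    def valid(self) -> bool:
        return not self.violations


def _version_ok_increment(counts, row, quota):
    return all(counts[k] + row[k] <= quota[k] for k in counts)


def build_design(
    pool: pd.DataFrame,
    n_versions: int = 8,
    trials_per_version: int = 36,
    seed: int = 0,
    congruency_tolerance: int = 1,
    max_restarts: int = 200,
) -> ExperimentDesign:
    """Assemble the balanced design from the pool manifest.

    Greedy per-slot assignment with shuffled candidates; a version that
    reaches a dead end is restarted with a fresh shuffle, up to
    ``max_restarts`` per version.  Trial order within a version is
    randomized.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    required = {"background_id", "target_source_id", "location_idx", "hue",
                "bg_category", "tg_category", "category_congruency", "depth_congruency"}
    missing = required - set(pool.columns)
    if missing:
        raise ValueError(f"pool manifest lacks columns: {sorted(missing)}")
    if len(pool) < trials_per_version:
        raise ValueError("pool too small for one version")

    cat_quota = _balanced_quota(trials_per_version, 3)
    cell_quota_base = trials_per_version / 4.0
    records = pool.to_dict("records")
    all_cells = [(a, b) for a in ("congruent", "incongruent") for b in ("congruent", "incongruent")]
    by_cell: dict[tuple[str, str], list[int]] = {c: [] for c in all_cells}
    for i, rec in enumerate(records):
        by_cell.setdefault((rec["category_congruency"], rec["depth_congruency"]), []).append(i)

    all_versions = []
    for v in range(1, n_versions + 1):
        version_rows = None
        binding = ""
        for _ in range(max_restarts):
            cell_pools = {c: [idx[k] for k in rng.permutation(len(idx))] for c, idx in by_cell.items()}
            chosen: list[int] = []
            chosen_set: set[int] = set()
            tg_cat_counts = {c: 0 for c in sorted(pool["tg_category"].unique())}
            bg_cat_counts = {c: 0 for c in sorted(pool["bg_category"].unique())}
            cell_counts = {c: 0 for c in all_cells}
            tg_use: dict[str, list] = {}
            bg_use: dict[str, list] = {}
            ok = True
            for _slot in range(trials_per_version):
                # fill the scarcest congruency cell first so the 2x2 stays
                # balanced as the version grows; within a cell prefer the
                # candidate whose categories are least represented so far
                cell_order = sorted(all_cells, key=lambda c: cell_counts[c])
                placed = False
                for want_cell in cell_order:
                    best_i, best_score = None, None
                    for i in cell_pools.get(want_cell, ()):
                        if i in chosen_set:
                            continue
                        row = records[i]
                        if not _admissible(
                            row, tg_cat_counts, bg_cat_counts, cell_counts,
                            tg_use, bg_use, cat_quota, cell_quota_base, congruency_tolerance,
                        ):
                            continue
                        score = tg_cat_counts[row["tg_category"]] + bg_cat_counts[row["bg_category"]]
                        if best_score is None or score < best_score:
                            best_i, best_score = i, score
                            if score == 0:
                                break
                    if best_i is not None:
                        _commit(records[best_i], best_i, chosen, tg_cat_counts, bg_cat_counts,
                                cell_counts, tg_use, bg_use)
                        chosen_set.add(best_i)
                        placed = True
                        break
                if not placed:
                    ok = False
                    binding = _binding_constraint(tg_cat_counts, bg_cat_counts, cell_counts)
                    break
            if ok:
                version_rows = chosen
                break
        if version_rows is None:
            raise ValueError(
                f"no valid design for version {v} after {max_restarts} restarts; "
                f"binding constraint: {binding or 'unknown'}"
            )
        dfv = pool.iloc[version_rows].copy()
        dfv["version"] = v
        dfv["trial_order"] = rng.permutation(len(dfv)) + 1
        all_versions.append(dfv.sort_values("trial_order"))

    trials = pd.concat(all_versions, ignore_index=True)
    design = ExperimentDesign(trials, n_versions, trials_per_version, congruency_tolerance)
    report = audit_design(design)
    if not report.valid:
        raise ValueError(f"solver produced an invalid design: {report.violations[:3]}")
    return design


def _balanced_quota(total: int, k: int) -> int:
    # max per level so counts can differ by at most 1
    return int(np.ceil(total / k))


def _admissible(row, tg_cat, bg_cat, cells, tg_use, bg_use, cat_quota, cell_base, tol) -> bool:
    if tg_cat[row["tg_category"]] + 1 > cat_quota:
        return False
    if bg_cat[row["bg_category"]] + 1 > cat_quota:
        return False
    cell = (row["category_congruency"], row["depth_congruency"])
    if cells.get(cell, 0) + 1 > int(np.floor(cell_base)) + tol:
        return False
    tg, bg = row["target_source_id"], row["background_id"]
    for img, use, partner_key in ((tg, tg_use, "background_id"), (bg, bg_use, "target_source_id")):
        prior = use.get(img, [])
        if len(prior) >= 2:
            return False
        for prev in prior:
            if (
                prev[partner_key] == row[partner_key]
                or prev["location_idx"] == row["location_idx"]
                or prev["hue"] == row["hue"]
            ):
                return False
    # an image may also appear once as target and once as background; that is allowed
    return True


def _commit(row, i, chosen, tg_cat, bg_cat, cells, tg_use, bg_use):
    chosen.append(i)
    tg_cat[row["tg_category"]] += 1
    bg_cat[row["bg_category"]] += 1
    cell = (row["category_congruency"], row["depth_congruency"])
    cells[cell] = cells.get(cell, 0) + 1
    tg_use.setdefault(row["target_source_id"], []).append(row)
    bg_use.setdefault(row["background_id"], []).append(row)


def _binding_constraint(tg_cat, bg_cat, cells) -> str:
    parts = [f"target-category counts {tg_cat}", f"background-category counts {bg_cat}",
             f"congruency cells {dict(cells)}"]
    return "; ".join(parts)


def audit_design(design: ExperimentDesign) -> ConstraintReport:
    """Check every design invariant; pure function, never raises."""
    violations: list[str] = []
    tables: dict = {}
    tol = design.congruency_tolerance
    for v in range(1, design.n_versions + 1):
        dfv = design.version(v)
        if len(dfv) != design.trials_per_version:
            violations.append(f"version {v}: {len(dfv)} trials, expected {design.trials_per_version}")
        for role, col in (("target", "tg_category"), ("background", "bg_category")):
            counts = dfv[col].value_counts()
            tables[(v, role)] = counts.to_dict()
            if len(counts) and counts.max() - counts.min() > 1:
                violations.append(f"version {v}: {role} categories unbalanced: {counts.to_dict()}")
        cells = dfv.groupby(["category_congruency", "depth_congruency"]).size()
        tables[(v, "congruency")] = cells.to_dict()
        if len(cells) < 4 or cells.max() - cells.min() > 2 * tol:
            violations.append(f"version {v}: congruency 2x2 unbalanced: {cells.to_dict()}")
        for role, col, partner in (
            ("target", "target_source_id", "background_id"),
            ("background", "background_id", "target_source_id"),
        ):
            counts = dfv[col].value_counts()
            for img, c in counts.items():
                if c > 2:
                    violations.append(f"version {v}: image {img} occurs {c}x as {role} (rule iii)")
                elif c == 2:
                    pair = dfv[dfv[col] == img]
                    if pair[partner].nunique() < 2:
                        violations.append(f"version {v}: repeated {role} {img} reuses partner image (rule iii)")
                    if pair["location_idx"].nunique() < 2:
                        violations.append(f"version {v}: repeated {role} {img} reuses location (rule iii)")
                    if pair["hue"].nunique() < 2:
                        violations.append(f"version {v}: repeated {role} {img} reuses hue (rule iii)")
    return ConstraintReport(balance_tables=tables, violations=violations)


def practice_trials(pool: pd.DataFrame, n: int = 5) -> pd.DataFrame:
    """Pick ``n`` practice trials ordered from easy to hard.

    Difficulty proxy: diff_luminance (a high target-background luminance
    contrast makes the target easy to spot), so trials are returned in
    non-increasing diff_luminance order.
    """
    if "diff_luminance" not in pool.columns:
        raise ValueError("pool lacks diff_luminance")
    if len(pool) < n:
        raise ValueError(f"pool of {len(pool)} cannot supply {n} practice trials")
    return pool.sort_values("diff_luminance", ascending=False).head(n).reset_index(drop=True)
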