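import json
import subprocess

import numpy as np
import pandas as pd
import pytest

from tapsync import (
    CONTRAST_NAMES,
    StudyDesign,
    aggregate_scores,
    fit_mixed_model,
    omnibus_tests,
    posthoc_contrasts,
    regress_clinical,
    simulate_score_table,
)
from tapsync.analysis import CONTRAST_FAMILY_SIZE
from tapsync.simulate import ParticipantRecord


def small_table(seed=0, **kw):
    design = StudyDesign(n_ci=12, n_hc=10, trials_per_condition=6, seed=seed, **kw)
    return simulate_score_table(design)


@pytest.fixture(scope="module")
def fitted():
    table = small_table(seed=7)
    return table, fit_mixed_model(table)


class TestAggregate:
    def make_scores(self, n_excluded):
        rows = []
        for i in range(10):
            rows.append(
                {
                    "participant_id": "p1",
                    "group": "CI",
                    "condition": "A",
                    "trial_index": i,
                    "logit_consistency": 0.5 if i >= n_excluded else None,
                    "excluded": i < n_excluded,
                }
            )
        return pd.DataFrame(rows)

    def test_filtering_and_counts(self):
        table = aggregate_scores(self.make_scores(2))
        assert len(table) == 8
        assert table.exclusion_counts["n_excluded"].sum() == 2
        assert table.exclusion_counts["n_total"].sum() == 10

    def test_all_excluded_participant_warns(self, caplog):
        with caplog.at_level("WARNING", logger="tapsync.analysis"):
            table = aggregate_scores(self.make_scores(10))
        assert len(table) == 0
        assert any("no usable trials" in m for m in caplog.messages)


class TestMixedModel:
    def test_single_participant_per_group_rejected(self):
        df = small_table(seed=1)
        one_each = df[df["participant_id"].isin(["CI01", "HC01"])]
        with pytest.raises(ValueError):
            fit_mixed_model(one_each)

    def test_omnibus_schema(self, fitted):
        _, fit = fitted
        omni = omnibus_tests(fit)
        assert list(omni["term"]) == ["group", "condition", "group:condition"]
        assert list(omni["df1"]) == [1, 3, 3]
        assert (omni["df2"] > 1).all() and (omni["p"] <= 1).all()

    def test_planted_condition_main_effect_only(self):
        cells = {
            g: {"A": 1.5, "V": -0.5, "AVsync": 1.0, "AVasync": -1.0} for g in ("CI", "HC")
        }
        table = small_table(seed=3, cell_logit=cells)
        omni = omnibus_tests(fit_mixed_model(table))
        by_term = omni.set_index("term")
        assert by_term.loc["condition", "p"] < 1e-6
        assert by_term.loc["group:condition", "F"] < 5.0

    def test_coding_invariance_under_level_relabelling(self, fitted):
        """Sum-to-zero omnibus F must not depend on factor level order."""
        table, fit = fitted
        omni0 = omnibus_tests(fit, df_method="between_within")
        relabel = {"A": "x1", "V": "x2", "AVsync": "x3", "AVasync": "x0"}
        df2 = table.copy()
        df2["condition"] = df2["condition"].map(relabel)
        omni1 = omnibus_tests(fit_mixed_model(df2), df_method="between_within")
        assert np.allclose(omni0["F"], omni1["F"], rtol=1e-4)

    def test_between_within_df(self, fitted):
        table, fit = fitted
        omni = omnibus_tests(fit, df_method="between_within")
        n_p = table["participant_id"].nunique()
        n = len(table)
        assert omni.set_index("term").loc["group", "df2"] == n_p - 2
        assert omni.set_index("term").loc["condition", "df2"] == n - n_p - 6


class TestContrasts:
    def test_family_of_eleven(self, fitted):
        _, fit = fitted
        contrasts = posthoc_contrasts(fit)
        assert len(contrasts) == CONTRAST_FAMILY_SIZE == 11
        assert tuple(c.name for c in contrasts) == CONTRAST_NAMES

    def test_bonferroni_cap_and_consistency(self, fitted):
        _, fit = fitted
        for c in posthoc_contrasts(fit):
            assert c.p_bonferroni == pytest.approx(min(1.0, 11 * c.p_raw))
            assert c.p_raw <= c.p_bonferroni <= 1.0

    def test_auditory_advantage_sign_recovery(self):
        # default cell means plant an auditory advantage in both groups
        table = small_table(seed=11)
        contrasts = {c.name: c for c in posthoc_contrasts(fit_mixed_model(table))}
        assert contrasts["A_CI - V_CI"].estimate > 0
        assert contrasts["A_HC - V_HC"].estimate > 0

    def test_missing_cell_reported_undefined(self):
        df = small_table(seed=5)
        df = df[~((df["group"] == "HC") & (df["condition"] == "AVsync"))]
        contrasts = posthoc_contrasts(fit_mixed_model(df))
        named = {c.name: c for c in contrasts}
        assert np.isnan(named["AVsync_HC - V_HC"].estimate)
        assert not np.isnan(named["A_CI - V_CI"].estimate)


R_ORACLE = r"""
suppressMessages({library(lmerTest); library(emmeans); library(pbkrtest); library(jsonlite)})
args <- commandArgs(trailingOnly = TRUE)
d <- read.delim(args[1], comment.char = "#")
d$group <- C(factor(d$group), contr.sum)
d$condition <- C(factor(d$condition), contr.sum)
m <- lmer(logit_consistency ~ group * condition + (1 + condition | participant_id),
          data = d, REML = TRUE,
          control = lmerControl(check.conv.singular = "ignore"))
a <- anova(m, type = 3, ddf = "Satterthwaite")
# Kenward-Roger tests of the sum-coded coefficient blocks (type 3)
kr <- lapply(list(group = 2, condition = 3:5, interaction = 6:8), function(cols) {
  L <- matrix(0, length(cols), 8); L[cbind(seq_along(cols), cols)] <- 1
  s <- KRmodcomp(m, L)$stats
  data.frame(F = s$Fstat, df2 = s$ddf)
})
emm <- emmeans(m, ~ group * condition)  # Kenward-Roger df by default
s <- as.data.frame(emm)
w <- with(s, (group == "CI" & condition == "AVsync") * 1 +
             (group == "CI" & condition == "V") * -1 +
             (group == "HC" & condition == "AVsync") * -1 +
             (group == "HC" & condition == "V") * 1)
ct <- as.data.frame(summary(contrast(emm, method = list(congruence = w))))
out <- list(
  anova = data.frame(term = rownames(a), F = a[["F value"]],
                     df1 = a[["NumDF"]], df2 = a[["DenDF"]]),
  kr = data.frame(term = names(kr), F = sapply(kr, `[[`, "F"),
                  df2 = sapply(kr, `[[`, "df2")),
  cells = s[, c("group", "condition", "emmean")],
  contrast = ct[, c("estimate", "SE", "t.ratio", "df")]
)
cat(toJSON(out, digits = 12))
"""


@pytest.mark.filterwarnings("ignore")
def test_agrees_with_lmer_emmeans_oracle(tmp_path, fitted):
    """Independent cross-check of the whole inference stack against
    R lmerTest (Satterthwaite type-3 anova) and emmeans."""
    table, fit = fitted
    tsv = tmp_path / "scores.tsv"
    table.to_csv(tsv, sep="\t", index=False)
    rfile = tmp_path / "oracle.R"
    rfile.write_text(R_ORACLE)
    proc = subprocess.run(
        ["Rscript", "--vanilla", str(rfile), str(tsv)],
        capture_output=True, text=True, timeout=300,
    )
    assert proc.returncode == 0, proc.stderr[-2000:]
    ref = json.loads(proc.stdout)

    # cell means (estimated marginal means)
    beta = np.asarray(fit.result.fe_params)
    for cell in ref["cells"]:
        mine = float(fit.cell_vector(cell["group"], cell["condition"]) @ beta)
        assert mine == pytest.approx(cell["emmean"], abs=2e-3)

    # type-3 omnibus F with Satterthwaite df vs lmerTest
    omni_sat = omnibus_tests(fit, "satterthwaite").set_index("term")
    for row in ref["anova"]:
        mine = omni_sat.loc[row["term"]]
        assert mine["F"] == pytest.approx(row["F"], rel=2e-2)
        assert mine["df2"] == pytest.approx(row["df2"], rel=0.15)

    # type-3 omnibus with the Kenward-Roger adjustment vs pbkrtest
    omni_kr = omnibus_tests(fit, "kenward_roger").set_index("term")
    kr_map = {"group": "group", "condition": "condition",
              "interaction": "group:condition"}
    for row in ref["kr"]:
        mine = omni_kr.loc[kr_map[row["term"]]]
        assert mine["F"] == pytest.approx(row["F"], rel=5e-3)
        assert mine["df2"] == pytest.approx(row["df2"], rel=2e-2)

    # the congruence contrast vs emmeans (Kenward-Roger)
    ct = ref["contrast"][0]
    mine = {c.name: c for c in posthoc_contrasts(fit, "kenward_roger")}[
        "(AVsync_CI - V_CI) - (AVsync_HC - V_HC)"
    ]
    assert mine.estimate == pytest.approx(ct["estimate"], abs=5e-3)
    assert mine.se == pytest.approx(ct["SE"], rel=5e-3)
    assert mine.t == pytest.approx(ct["t.ratio"], rel=1e-2)
    assert mine.df == pytest.approx(ct["df"], rel=2e-2)


class TestClinicalRegression:
    def make_participants(self, onsets, pre=None):
        out = []
        for i, o in enumerate(onsets):
            is_pre = pre is not None and i in pre
            out.append(
                ParticipantRecord(
                    id=f"CI{i + 1:02d}", group="CI", age=50.0,
                    onset_age=None if is_pre else o, pre_linguistic=is_pre,
                    deafness_duration=10.0 + i, implantation_age=40.0, ci_use_years=5.0,
                )
            )
        return out

    def make_table(self, y_by_pid, condition="V"):
        rows = [
            {"participant_id": pid, "group": "CI", "condition": condition,
             "trial": 0, "logit_consistency": y}
            for pid, y in y_by_pid.items()
        ]
        return pd.DataFrame(rows)

    def test_pre_linguistic_coded_as_two_years(self):
        onsets = [10, 20, 30, 40, 50, 60]
        parts = self.make_participants(onsets, pre={0})
        coded = [2.0] + onsets[1:]
        slope_true = -0.05
        y = {p.id: slope_true * x for p, x in zip(parts, coded)}
        res = regress_clinical(self.make_table(y), parts, "V_CI", "onset_age")
        assert res.slope == pytest.approx(slope_true, abs=1e-9)
        assert res.df == len(parts) - 2

    def test_matches_ols_oracle(self, rng):
        onsets = list(rng.uniform(1, 50, 12))
        parts = self.make_participants(onsets)
        y = {p.id: float(-0.04 * o + rng.normal(0, 0.5)) for p, o in zip(parts, onsets)}
        res = regress_clinical(self.make_table(y), parts, "V_CI", "onset_age")
        # independent closed-form OLS slope
        x = np.array(onsets)
        yy = np.array([y[p.id] for p in parts])
        b = np.cov(x, yy, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert res.slope == pytest.approx(b, abs=1e-10)

    def test_planted_slope_recovery(self, rng):
        slopes = []
        for _ in range(200):
            onsets = rng.uniform(1, 50, 20)
            parts = self.make_participants(onsets)
            y = {p.id: float(-0.04 * o + rng.normal(0, 0.6)) for p, o in zip(parts, onsets)}
            slopes.append(
                regress_clinical(self.make_table(y), parts, "V_CI", "onset_age").slope
            )
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert np.mean(slopes) == pytest.approx(-0.04, abs=3 * se)

    def test_zero_variance_predictor_rejected(self):
        parts = self.make_participants([5, 5, 5, 5, 5])
        y = {p.id: 0.1 for p in parts}
        with pytest.raises(ValueError):
            regress_clinical(self.make_table(y), parts, "V_CI", "onset_age")

    def test_too_few_participants_rejected(self):
        parts = self.make_participants([1, 2, 3])
        y = {p.id: 0.1 for p in parts}
        with pytest.raises(ValueError):
            regress_clinical(self.make_table(y), parts, "V_CI", "onset_age")

    def test_congruence_outcome(self):
        parts = self.make_participants([10, 20, 30, 40])
        rows = []
        for i, p in enumerate(parts):
            for cond, val in (("AVsync", 1.0 + 0.1 * i), ("V", 0.5)):
                rows.append({"participant_id": p.id, "group": "CI", "condition": cond,
                             "trial": 0, "logit_consistency": val})
        res = regress_clinical(
            pd.DataFrame(rows), parts, "AVsync_minus_V", "deafness_duration"
        )
        assert res.slope == pytest.approx(0.1, abs=1e-9)  # duration steps by 1
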