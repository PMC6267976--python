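import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import cwmcats as cc
from cwmcats.errors import DegenerateDesignError, ValidationError


def classical_two_way_f(y, a, b):
    """Sequential two-way ANOVA pseudo-F oracle from raw sums of squares."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame({"y": y, "a": a, "b": b})
    model = ols("y ~ C(a) * C(b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    return {
        "A": float(table.loc["C(a)", "F"]),
        "B": float(table.loc["C(b)", "F"]),
        "A:B": float(table.loc["C(a):C(b)", "F"]),
    }


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ([1.0, 0.0, 1.0], [1.0, 0.0, 1.0], 0.0),
        ([1.0, 0.0], [0.0, 1.0], 1.0),
        ([1.0, 0.0, 1.0], [0.0, 1.0, 1.0], 0.5),
    ],
)
def test_bray_curtis_values(x, y, expected):
    m = pd.DataFrame([x, y], index=["s1", "s2"], columns=[f"sp{i}" for i in range(len(x))])
    d = cc.bray_curtis(m)
    assert d["s1", "s2"] == pytest.approx(expected)


def test_bray_curtis_rejects_empty_rows():
    m = pd.DataFrame([[0.0, 0.0], [1.0, 2.0]], index=["z", "s"], columns=["a", "b"])
    with pytest.raises(ValidationError):
        cc.bray_curtis(m)


def test_univariate_equals_classical_anova_f():
    """Euclidean-distance pseudo-F == textbook sequential two-way F."""
    rng = np.random.default_rng(17)
    for rep in range(10):
        n_per = int(rng.integers(3, 7))
        a = np.repeat(["a1", "a2"], 2 * n_per)
        b = np.tile(np.repeat(["b1", "b2"], n_per), 2)
        y = rng.normal(0, 1, len(a)) + (a == "a1") * rng.normal(0, 1)
        res = cc.permanova_univariate(
            pd.Series(y), pd.Series(a, name="A"), pd.Series(b, name="B"), n_perm=9, seed=rep
        )
        oracle = classical_two_way_f(y, a, b)
        assert res.table.loc["A", "pseudo_f"] == pytest.approx(oracle["A"], abs=1e-8)
        assert res.table.loc["B", "pseudo_f"] == pytest.approx(oracle["B"], abs=1e-8)
        assert res.table.loc["A:B", "pseudo_f"] == pytest.approx(oracle["A:B"], abs=1e-8)


def test_ss_additivity_and_r2_partition():
    rng = np.random.default_rng(23)
    n = 24
    a = pd.Series(np.repeat(["sun", "shade"], n // 2), name="light")
    b = pd.Series(np.tile(np.repeat(["lime", "basalt"], n // 4), 2), name="soil")
    comm = pd.DataFrame(
        rng.dirichlet(np.ones(5), size=n), index=[f"p{i}" for i in range(n)]
    )
    res = cc.permanova_2way(cc.bray_curtis(comm), a, b, n_perm=99, seed=0)
    t = res.table
    parts = t.loc[["light", "soil", "light:soil", "Residual"], "ss"].sum()
    assert parts == pytest.approx(t.loc["Total", "ss"], abs=1e-8)
    assert t.loc[["light", "soil", "light:soil", "Residual"], "r2"].sum() == pytest.approx(1.0)


def test_mcardle_anderson_identity():
    """Euclidean PerMANOVA on multivariate data partitions the summed
    per-variable classical ANOVA sums of squares."""
    rng = np.random.default_rng(31)
    n = 20
    a = np.repeat(["a1", "a2"], 10)
    b = np.tile(np.repeat(["b1", "b2"], 5), 2)
    y = rng.normal(0, 1, (n, 3))
    res = cc.permanova_2way(
        cc.euclidean_distance(y), pd.Series(a, name="A"), pd.Series(b, name="B"),
        n_perm=9, seed=0,
    )
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    ss_a = 0.0
    for k in range(3):
        df = pd.DataFrame({"y": y[:, k], "a": a, "b": b})
        table = sm.stats.anova_lm(ols("y ~ C(a) * C(b)", data=df).fit(), typ=1)
        ss_a += float(table.loc["C(a)", "sum_sq"])
    assert res.table.loc["A", "ss"] == pytest.approx(ss_a, abs=1e-8)


def test_constant_response_degenerate():
    a = pd.Series(["x", "x", "y", "y"] * 2)
    b = pd.Series(["u", "v"] * 4)
    with pytest.raises(DegenerateDesignError):
        cc.permanova_univariate(np.ones(8), a, b, n_perm=9, seed=0)


def test_empty_cell_rejected():
    a = pd.Series(["x"] * 4 + ["y"] * 4)
    b = pd.Series(["u"] * 4 + ["u"] * 4)  # factor b has one level
    with pytest.raises(ValidationError):
        cc.permanova_univariate(np.arange(8.0), a, b, n_perm=9, seed=0)


def test_p_invariant_to_level_relabeling():
    rng = np.random.default_rng(5)
    y = rng.normal(0, 1, 16)
    a = pd.Series(np.repeat(["sun", "shade"], 8), name="A")
    b = pd.Series(np.tile(np.repeat(["l", "b"], 4), 2), name="B")
    r1 = cc.permanova_univariate(y, a, b, n_perm=199, seed=9)
    r2 = cc.permanova_univariate(y, a.map({"sun": "S", "shade": "H"}), b, n_perm=199, seed=9)
    assert r1.table.loc["A", "p"] == r2.table.loc["A", "p"]
    assert r1.table.loc["A", "pseudo_f"] == pytest.approx(r2.table.loc["A", "pseudo_f"])


def test_permutation_type_one_error_nominal():
    """Under a true null the permutation p rejects at ~alpha."""
    rng = np.random.default_rng(77)
    a = pd.Series(np.repeat(["a1", "a2"], 20), name="A")
    b = pd.Series(np.tile(np.repeat(["b1", "b2"], 10), 2), name="B")
    n_sim = 120
    rej = 0
    for _ in range(n_sim):
        y = rng.normal(0, 1, 40)
        res = cc.permanova_univariate(y, a, b, n_perm=99, seed=int(rng.integers(2**31)))
        if res.table.loc["A", "p"] <= 0.05:
            rej += 1
    assert rej / n_sim <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_sim)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_against_vegan_adonis2(tmp_path, experiment):
    """Independent oracle: vegan's adonis2 on a synthetic experiment."""
    rel = cc.relativize(experiment.counts).drop_zero_rows()
    design = experiment.design.loc[rel.data.index]
    res = cc.permanova_2way(
        cc.bray_curtis(rel),
        design["light"].rename("light"),
        design["soil"].rename("soil"),
        n_perm=99,
        seed=0,
    )
    comm_csv, design_csv, out_csv = (
        tmp_path / "c.csv", tmp_path / "d.csv", tmp_path / "o.csv",
    )
    rel.data.to_csv(comm_csv, index=False)
    design[["light", "soil"]].to_csv(design_csv, index=False)
    script = tmp_path / "adonis.R"
    script.write_text(
        f"""
        suppressMessages(library(vegan))
        comm <- read.csv("{comm_csv}")
        design <- read.csv("{design_csv}")
        fit <- adonis2(comm ~ light * soil, data=design, method="bray",
                       permutations=99, by="terms")
        write.csv(data.frame(term=rownames(fit), ss=fit$SumOfSqs, f=fit$F, r2=fit$R2),
                  "{out_csv}", row.names=FALSE)
        """
    )
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    ref = pd.read_csv(out_csv).set_index("term")
    for ours, theirs in [("light", "light"), ("soil", "soil"), ("light:soil", "light:soil")]:
        assert res.table.loc[ours, "ss"] == pytest.approx(ref.loc[theirs, "ss"], rel=1e-6)
        assert res.table.loc[ours, "pseudo_f"] == pytest.approx(ref.loc[theirs, "f"], rel=1e-6)
        assert res.table.loc[ours, "r2"] == pytest.approx(ref.loc[theirs, "r2"], rel=1e-6)
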