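import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import homeotrip as ht
from ._oracles import exact_test_oracle
from .conftest import make_count_matrix


class TestExactTest:
    def test_equal_counts_give_p_one(self):
        assert ht.nb_exact_test([30, 30], [30, 30], 0.2) == pytest.approx(1.0)

    def test_poisson_limit_is_binomial(self):
        # counts 10 vs 0, one replicate each: Binomial(10, 1/2), two-sided 2/1024
        assert ht.nb_exact_test([10], [0], 0.0) == pytest.approx(2 / 1024, abs=1e-12)

    @pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
    def test_matches_enumeration_oracle(self, phi, rng):
        for _ in range(60):
            n_a, n_b = rng.integers(1, 4, 2)
            ya = list(rng.integers(0, 60, n_a))
            yb = list(rng.integers(0, 60, n_b))
            p_impl = ht.nb_exact_test(ya, yb, phi)
            assert p_impl == pytest.approx(exact_test_oracle(ya, yb, phi), abs=1e-10)

    def test_zero_total_gives_p_one(self):
        assert ht.nb_exact_test([0, 0], [0, 0], 0.3) == 1.0

    def test_monotone_away_from_conditional_mode(self):
        # with group B fixed, moving group A's total away from the mode never raises p
        yb = [40, 40]
        pvals = [ht.nb_exact_test([40 + d, 40], yb, 0.1) for d in range(0, 60, 5)]
        assert all(a >= b - 1e-12 for a, b in zip(pvals, pvals[1:]))

    def test_symmetric_in_groups(self):
        assert ht.nb_exact_test([12, 9], [30, 35], 0.2) == pytest.approx(
            ht.nb_exact_test([30, 35], [12, 9], 0.2), abs=1e-12
        )


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_matches_edger_exact_test(tmp_path):
    """Independent cross-check against edgeR's exactTest (smallp region).

    Equal libraries and a fixed dispersion make edgeR's pseudo-counts the
    raw counts, so the two conditional tests must agree numerically.
    """
    rows = [([12, 15], [40, 44]), ([100, 95], [60, 70]), ([5, 0], [9, 14]), ([30, 31], [29, 33])]
    script = tmp_path / "edger.R"
    script.write_text(
        textwrap.dedent(
            """
            suppressMessages(library(edgeR))
            counts <- matrix(c(12,15,40,44, 100,95,60,70, 5,0,9,14, 30,31,29,33), nrow=4, byrow=TRUE)
            d <- DGEList(counts=counts, group=factor(c("A","A","B","B")), lib.size=rep(1000,4))
            res <- exactTest(d, dispersion=0.1, rejection.region="smallp")
            cat(sprintf("%.15g\\n", res$table$PValue))
            """
        )
    )
    try:
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=240, check=True
        )
    except (subprocess.CalledProcessError, subprocess.TimeoutExpired) as exc:
        pytest.skip(f"edgeR not usable: {exc}")
    edger_p = [float(x) for x in out.stdout.split()]
    ours = [ht.nb_exact_test(ya, yb, 0.1) for ya, yb in rows]
    np.testing.assert_allclose(ours, edger_p, rtol=1e-8)


class TestDispersion:
    def test_identical_replicates_give_zero(self, rng):
        mu = rng.integers(20, 300, 400)
        y = np.tile(mu[:, None], (1, 4))
        cm = make_count_matrix({s: y[:, i] for i, s in enumerate(["c1", "c2", "h1", "h2"])})
        assert ht.estimate_common_dispersion(cm).dispersion == 0.0

    def test_recovers_simulated_dispersion(self, rng):
        phi = 0.4
        mu = rng.lognormal(np.log(100), 0.5, 2000)
        y = rng.poisson(rng.gamma(1 / phi, mu[:, None] * phi, (2000, 4)))
        cm = make_count_matrix({s: y[:, i] for i, s in enumerate(["c1", "c2", "h1", "h2"])})
        est = ht.estimate_common_dispersion(cm).dispersion
        assert est == pytest.approx(phi, rel=0.25)

    def test_invariant_to_gene_order(self, rng):
        mu = rng.lognormal(np.log(80), 0.4, 300)
        y = rng.poisson(rng.gamma(5.0, mu[:, None] / 5.0, (300, 4)))
        cm = make_count_matrix({s: y[:, i] for i, s in enumerate(["c1", "c2", "h1", "h2"])})
        perm = rng.permutation(cm.counts.index)
        cm_perm = ht.CountMatrix(cm.counts.loc[perm], cm.samples)
        a = ht.estimate_common_dispersion(cm).dispersion
        b = ht.estimate_common_dispersion(cm_perm).dispersion
        assert a == pytest.approx(b, rel=1e-6)

    def test_all_zero_counts_give_zero_with_warning(self, caplog):
        cm = make_count_matrix({s: [0, 0, 0] for s in ["c1", "c2", "h1", "h2"]})
        assert ht.estimate_common_dispersion(cm).dispersion == 0.0


class TestCalls:
    def test_bh_single_p_unchanged(self):
        assert ht.bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_bh_hand_example(self):
        np.testing.assert_allclose(ht.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_bh_never_below_p(self, rng):
        p = rng.uniform(0, 1, 50)
        assert (ht.bh_adjust(p) >= p - 1e-15).all()

    @pytest.mark.parametrize(
        "lfc,p,expected",
        [(1.2, 0.005, "up"), (1.0, 0.001, "ns"), (-3.0, 0.02, "ns"), (-1.5, 0.004, "down")],
    )
    def test_call_thresholds_are_strict(self, lfc, p, expected):
        df = pd.DataFrame({"log2FC": [lfc], "pvalue": [p]}, index=["g"])
        assert ht.call_de(df)["call"].iloc[0] == expected

    def test_table_calls_satisfy_invariants(self, small_run):
        de = small_run.de
        up = de[de["call"] == "up"]
        assert (up["log2FC"] > 1).all() and (up["pvalue"] < 0.01).all()
        down = de[de["call"] == "down"]
        assert (down["log2FC"] < -1).all() and (down["pvalue"] < 0.01).all()
        assert de["pvalue"].between(0, 1).all()
        assert (de["qvalue"] >= de["pvalue"] - 1e-15).all()
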