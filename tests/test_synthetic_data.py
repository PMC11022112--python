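"""The synthetic-data generator: norms, forward model, and tampering."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import curve_fit

from valtrans.screening import Pcl5Response, flag_outlier, score_pcl5
from valtrans.synthetic_data import (
    GeneratorConfig,
    GroupParams,
    generate_norms,
    generate_participants,
    inject_outliers,
)


class TestGenerateNorms:
    def test_study_layout(self):
        norms = generate_norms(35, 5, seed=1)
        assert len(norms) == 40
        neg = norms.head(35)["valence_mean"]
        assert neg.min() == pytest.approx(1.33)
        assert neg.max() == pytest.approx(5.0)
        assert neg.is_monotonic_increasing
        pos = norms.tail(5)["valence_mean"]
        assert pos.min() >= 5.63 and pos.max() <= 7.09
        assert (norms["valence_sd"] > 0).all()

    def test_two_image_endpoints_exact(self):
        norms = generate_norms(2, 0, seed=9, jitter=0.0)
        np.testing.assert_allclose(norms["valence_mean"], [1.33, 5.0])

    def test_deterministic(self):
        a = generate_norms(35, 5, seed=7)
        b = generate_norms(35, 5, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_images_raises(self):
        with pytest.raises(ValueError):
            generate_norms(1, 0, seed=0)


class TestGenerateParticipants:
    def test_ratings_in_unit_interval_and_vectors_valid(self, small_dataset):
        ratings = small_dataset["ratings"]
        assert ratings["rating"].between(0, 1).all()
        q = small_dataset["questionnaires"]
        for _, row in q.iterrows():
            items = tuple(int(row[f"pcl5_{i:02d}"]) for i in range(1, 21))
            Pcl5Response(str(row["participant_id"]), items)  # validates

    def test_groups_reproduced_by_screening_rule(self, small_dataset):
        """Intended group == screened group for every participant."""
        q = small_dataset["questionnaires"]
        truth = small_dataset["truth"].set_index("participant_id")
        for _, row in q.iterrows():
            items = tuple(int(row[f"pcl5_{i:02d}"]) for i in range(1, 21))
            d = score_pcl5(Pcl5Response(str(row["participant_id"]), items))
            assert d.group == truth.loc[row["participant_id"], "group"]

    def test_en_coupling_positive_correlation(self):
        norms = generate_norms(10, 0, seed=2)
        cfg = GeneratorConfig(
            n_per_group=40, seed=2, n_images=10, n_positive=0, en_slope_coeff=0.3
        )
        _, _, truth = generate_participants(cfg, norms)
        r = np.corrcoef(truth["B"], truth["en_z"])[0, 1]
        assert r > 0.1

    def test_noiseless_limit_reproduces_group_curve(self):
        """With vanishing noise and SDs all ratings equal the group 5-PL."""
        norms = generate_norms(8, 0, seed=3, jitter=0.0)
        tiny = 1e-9
        gp = dict(a_sd=tiny, sd_b=tiny, sd_c=tiny, sd_d=tiny, sd_g=tiny)
        cfg = GeneratorConfig(
            n_per_group=3,
            seed=3,
            n_images=8,
            n_positive=0,
            noise_sd=1e-12,
            en_slope_coeff=0.0,
            groups={"TEC": GroupParams(mu_b=1.2, **gp)},
        )
        ratings, _, truth = generate_participants(cfg, norms)
        wide = ratings.pivot(index="participant_id", columns="image_id", values="rating")
        spread = wide.to_numpy().std(axis=0)
        assert spread.max() < 1e-6  # all participants identical
        assert truth["b"].std() < 1e-6

    def test_group_slope_direction_recovered_by_least_squares(self):
        """pPTSD group (higher true mu_b) shows higher fitted free slopes."""
        norms = generate_norms(20, 0, seed=4)
        cfg = GeneratorConfig(
            n_per_group=25,
            seed=4,
            n_images=20,
            n_positive=0,
            noise_sd=0.02,
            en_slope_coeff=0.0,
            groups={
                "TEC": GroupParams(mu_b=1.2, sd_b=0.1, sd_g=0.05),
                "pPTSD": GroupParams(mu_b=1.45, sd_b=0.1, sd_g=0.05),
            },
        )
        ratings, _, truth = generate_participants(cfg, norms)

        # asymmetry fixed near its true value: the free b-g tradeoff would
        # otherwise swamp a 0.25 slope gap in per-participant fits
        def f(x, a, b, c, d):
            return d + (a - d) / (1.0 + (x / c) ** b) ** 2.0

        slopes = {}
        for pid, grp in ratings.groupby("participant_id"):
            y = grp.sort_values("image_id")["rating"].to_numpy()
            xs = norms.sort_values("image_id")["valence_mean"].to_numpy()
            try:
                popt, _ = curve_fit(
                    f,
                    xs,
                    y,
                    p0=[0.08, 1.3, 2.7, 0.58],
                    bounds=([0, 0.2, 0.5, 0.3], [0.5, 6, 5, 1]),
                    maxfev=5000,
                )
                slopes[pid] = popt[1]
            except RuntimeError:
                continue
        t = truth.set_index("participant_id")
        s = pd.Series(slopes)
        mean_tec = s[t.loc[s.index, "group"] == "TEC"].mean()
        mean_ptsd = s[t.loc[s.index, "group"] == "pPTSD"].mean()
        assert mean_ptsd > mean_tec

    def test_deterministic_given_seed(self, small_dataset):
        cfg = small_dataset["cfg"]
        norms = small_dataset["norms"]
        r2, q2, t2 = generate_participants(cfg, norms)
        pd.testing.assert_frame_equal(small_dataset["ratings"], r2)
        pd.testing.assert_frame_equal(small_dataset["questionnaires"], q2)
        pd.testing.assert_frame_equal(small_dataset["truth"], t2)

    def test_out_of_range_config_rejected(self):
        with pytest.raises(ValueError, match="VAS range"):
            GeneratorConfig(
                n_per_group=3, seed=0, groups={"TEC": GroupParams(mu_b=1.2, mu_d=0.95)}
            )


class TestInjectOutliers:
    def test_three_tampered_images_trigger_exclusion(self, small_dataset):
        tampered, pids = inject_outliers(
            small_dataset["ratings"], small_dataset["norms"], 2, 3, seed=5
        )
        assert len(pids) == 2
        for pid in pids:
            v = flag_outlier(
                tampered[tampered["participant_id"] == pid], small_dataset["norms"]
            )
            assert v.excluded

    def test_two_tampered_images_do_not(self, small_dataset):
        tampered, pids = inject_outliers(
            small_dataset["ratings"], small_dataset["norms"], 2, 2, seed=5
        )
        for pid in pids:
            v = flag_outlier(
                tampered[tampered["participant_id"] == pid], small_dataset["norms"]
            )
            assert not v.excluded

    def test_zero_participants_is_identity(self, small_dataset):
        tampered, pids = inject_outliers(
            small_dataset["ratings"], small_dataset["norms"], 0, 3, seed=5
        )
        assert pids == []
        pd.testing.assert_frame_equal(tampered, small_dataset["ratings"])

    def test_untouched_records_unchanged(self, small_dataset):
        tampered, pids = inject_outliers(
            small_dataset["ratings"], small_dataset["norms"], 1, 3, seed=6
        )
        rest = tampered[~tampered["participant_id"].isin(pids)]
        orig = small_dataset["ratings"]
        pd.testing.assert_frame_equal(
            rest.reset_index(drop=True),
            orig[~orig["participant_id"].isin(pids)].reset_index(drop=True),
        )

    def test_too_many_participants_raises(self, small_dataset):
        with pytest.raises(ValueError, match="only"):
            inject_outliers(
                small_dataset["ratings"], small_dataset["norms"], 999, 3, seed=0
            )
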