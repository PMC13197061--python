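"""End-to-end desk-scale study: synthesize, train, reconstruct, score, evaluate.

This is the package's reference experiment, sized for a single CPU: an
order-2 synthetic cohort (100 healthy controls for training; 20 held-out
controls and 20 atrophied "AD" subjects for testing), a conditional and an
identically trained unconditional diffusion model, pseudo-healthy
reconstruction at ``t_start = T/2`` with N=10 samples per subject, ROI
abnormality scoring, the conditioning ablation (reconstruction MSE / SSIM),
and CN-vs-AD classification from the score vectors.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .estimators import ConditionalSurfaceDDPM, cohort_arrays
from .geometry import build_icosphere, make_parcellation
from .metrics import mse, ssim_sphere
from .normative import classification_eval
from .synthetic import CohortSpec, make_cohort

__all__ = ["run_normative_study"]


def run_normative_study(
    seed: int = 0,
    order: int = 2,
    n_train: int = 100,
    n_test_cn: int = 20,
    n_test_ad: int = 20,
    T: int = 250,
    train_steps: int = 2000,
    batch_size: int = 16,
    learning_rate: float = 1e-3,
    hidden_dims: tuple = (16, 32, 48),
    n_samples: int = 10,
    t_start: int | None = None,
    delta: float = 0.5,
    n_rois: int = 34,
    run_ablation: bool = True,
    run_classification: bool = True,
    verbose: bool = False,
) -> dict:
    """Run the full synthetic normative-modeling study; returns a result dict.

    Keys include ``ad_mean_z_disease`` (mean abnormality score of AD subjects
    in the atrophied ROIs — negative when atrophy is detected),
    ``sign_test_p`` (one-sided sign test that AD disease-ROI scores are
    negative), the conditional/unconditional ablation metrics, and the
    CN-vs-AD classification report.
    """
    seed = int(seed) % (2**31 - 1)
    ico = build_icosphere(order)
    atlas = make_parcellation(ico, n_rois, seed=0)

    train_spec = CohortSpec(
        n_subjects=n_train, order=order, delta=delta, n_rois=n_rois, seed=seed
    )
    test_spec = CohortSpec(
        n_subjects=n_test_cn + n_test_ad,
        order=order,
        delta=delta,
        n_rois=n_rois,
        group_fractions={
            "CN": n_test_cn / (n_test_cn + n_test_ad),
            "AD": n_test_ad / (n_test_cn + n_test_ad),
        },
        seed=seed + 1,
    )
    train_subjects, _ = make_cohort(train_spec, ico=ico, parcellation=atlas)
    test_subjects, _ = make_cohort(test_spec, ico=ico, parcellation=atlas)
    test_cn = [s for s in test_subjects if s.group == "CN"]
    test_ad = [s for s in test_subjects if s.group == "AD"]

    def build(use_mask: bool, rs: int) -> ConditionalSurfaceDDPM:
        return ConditionalSurfaceDDPM(
            order=order,
            n_timesteps=T,
            hidden_dims=hidden_dims,
            use_mask=use_mask,
            n_steps=train_steps,
            batch_size=batch_size,
            learning_rate=learning_rate,
            augment=True,
            random_state=rs,
        )

    if verbose:
        print(f"training conditional model ({train_steps} steps) ...")
    model = build(use_mask=True, rs=seed).fit(train_subjects)

    results: dict = {
        "seed": seed,
        "order": order,
        "n_vertices": ico.n_vertices,
        "final_train_loss": float(np.mean(model.loss_history_[-100:])),
        "disease_rois": list(train_spec.disease_roi_ids),
    }

    # --- validation v-loss vs the predict-zero baseline ------------------
    from .diffusion import q_sample, v_target

    val = model.standardized_features(test_cn)
    val_rng = np.random.default_rng(seed + 23)
    t_val = val_rng.integers(1, model.schedule_.T + 1, size=val.shape[0] * 8)
    x_rep = np.tile(val, (8, 1, 1))
    eps = val_rng.standard_normal(x_rep.shape)
    xt = q_sample(x_rep, t_val, eps, model.schedule_)
    target = v_target(x_rep, eps, t_val, model.schedule_)
    cn_arrays = {
        k: np.tile(v, (8,) + (1,) * (v.ndim - 1))
        for k, v in cohort_arrays(test_cn).items()
    }
    v_hat = model.unet_.predict_v(xt, t_val, model._conditions(cn_arrays))
    results["val_v_loss"] = float(np.mean((v_hat - target) ** 2))
    results["val_v_loss_zero"] = float(np.mean(target**2))

    # --- pseudo-healthy reconstruction of the whole test set -------------
    if verbose:
        print("reconstructing test subjects (diffusion reference sets) ...")
    from .normative import abnormal_scores

    recon_rng = np.random.default_rng(seed + 17)
    recon = model.reconstruct(
        test_subjects, n_samples=n_samples, t_start=t_start, rng=recon_rng
    )  # (N, B, V, C) standardized
    feats_std = model.standardized_features(test_subjects)
    z_all = np.stack(
        [
            abnormal_scores(
                feats_std[b, :, 0], recon[:, b, :, 0], atlas,
                subject_id=test_subjects[b].subject_id,
            ).z
            for b in range(len(test_subjects))
        ]
    )
    groups = np.array([s.group for s in test_subjects])
    disease = np.array(train_spec.disease_roi_ids)
    healthy_rois = np.setdiff1d(np.arange(n_rois), disease)

    z_ad = z_all[groups == "AD"]
    z_cn = z_all[groups == "CN"]
    ad_disease_mean = z_ad[:, disease].mean(axis=1)  # per AD subject
    results["ad_mean_z_disease"] = float(ad_disease_mean.mean())
    results["ad_mean_abs_z_healthy"] = float(np.abs(z_ad[:, healthy_rois]).mean())
    results["cn_mean_z_disease"] = float(z_cn[:, disease].mean())
    n_neg = int((ad_disease_mean < 0).sum())
    results["sign_test_p"] = float(
        sps.binomtest(n_neg, len(ad_disease_mean), 0.5, alternative="greater").pvalue
    )

    # --- conditioning ablation on held-out controls ----------------------
    if run_ablation:
        if verbose:
            print(f"training unconditional model ({train_steps} steps) ...")
        model_uncond = build(use_mask=False, rs=seed).fit(train_subjects)

        def summarize(recon_set, truth) -> tuple[float, float]:
            mses, ssims = [], []
            for b in range(truth.shape[0]):
                for k in range(recon_set.shape[0]):
                    mses.append(mse(truth[b, :, 0], recon_set[k, b, :, 0]))
                    ssims.append(ssim_sphere(truth[b, :, 0], recon_set[k, b, :, 0], ico))
            return float(np.mean(mses)), float(np.mean(ssims))

        cn_idx = np.flatnonzero(groups == "CN")
        mse_c, ssim_c = summarize(recon[:, cn_idx], feats_std[cn_idx])
        recon_u = model_uncond.reconstruct(
            test_cn, n_samples=n_samples, t_start=t_start,
            rng=np.random.default_rng(seed + 17),
        )
        mse_u, ssim_u = summarize(recon_u, model_uncond.standardized_features(test_cn))
        results.update(
            {
                "cond_ct_mse": mse_c,
                "cond_ct_ssim": ssim_c,
                "uncond_ct_mse": mse_u,
                "uncond_ct_ssim": ssim_u,
            }
        )

    # --- CN vs AD classification from score vectors ----------------------
    if run_classification:
        finite = np.all(np.isfinite(z_all), axis=0)
        max_folds = int(min(np.unique(groups, return_counts=True)[1]))
        report = classification_eval(
            z_all[:, finite], groups, folds=min(10, max_folds), seed=seed
        )
        results["cn_vs_ad_accuracy"] = report["accuracy"]
        results["cn_vs_ad_precision"] = report["precision"]
        results["cn_vs_ad_recall"] = report["recall"]

    return results
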