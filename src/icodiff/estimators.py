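"""Scikit-learn-style estimators wrapping the diffusion normative pipeline.

:class:`ConditionalSurfaceDDPM` is the generative half — ``fit`` trains the
conditional spherical diffusion model on a (healthy) cohort, after which
``sample`` draws new feature maps and ``reconstruct`` produces pseudo-healthy
partial-noise reconstructions of test subjects.  :class:`NormativeScorer` is
the analysis half — a transformer whose ``transform`` turns subjects into
per-ROI abnormality z-score vectors against either diffusion ("ddpm") or
age-matched real-subject ("template") reference sets.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .denoiser import ConditionSet, DenoiserConfig, SphericalUNet, train_denoiser
from .diffusion import cosine_schedule, partial_reconstruct, sample_chain
from .geometry import build_icosphere, icosahedral_symmetries
from .io import ChannelStats, standardize_channels
from .normative import abnormal_scores, template_reference

__all__ = [
    "ConditionalSurfaceDDPM",
    "NormativeScorer",
    "cohort_arrays",
    "save_model",
    "load_model",
]


def cohort_arrays(subjects: list) -> dict:
    """Stack a list of SubjectRecords into dense arrays.

    Ages follow the unit-scaled convention (years / 100) expected by the
    demographic conditioning MLPs.
    """
    return {
        "features": np.stack([s.features for s in subjects]).astype(np.float64),
        "mask": np.stack([s.mask for s in subjects]).astype(np.float64),
        "age": np.array([s.age for s in subjects], dtype=np.float64) / 100.0,
        "sex": np.array([s.sex for s in subjects], dtype=np.float64),
    }


class ConditionalSurfaceDDPM(BaseEstimator):
    """Conditional spherical DDPM with v-prediction.

    Parameters mirror the pipeline's knobs: icosphere ``order``, schedule
    length ``n_timesteps`` (cosine schedule), UNet widths/depth/attention,
    the two conditioning switches, and the desk-scale training loop (Adam).
    The full-cortex configuration is order 6, T=1000, widths (128, 256, 512);
    defaults here are sized for order-2 synthetic cohorts.

    Fitted attributes: ``unet_``, ``schedule_``, ``channel_stats_``,
    ``loss_history_``, ``ico_``, ``n_channels_``.
    """

    def __init__(
        self,
        order: int = 2,
        n_timesteps: int = 250,
        schedule_s: float = 0.008,
        beta_clip: float = 0.999,
        hidden_dims: tuple = (16, 32, 48),
        n_levels: int = 3,
        resblocks_per_level: int = 2,
        attention_levels: tuple = (1, 2),
        time_embed_dim: int = 64,
        use_mask: bool = True,
        use_demographics: bool = True,
        n_steps: int = 2000,
        batch_size: int = 16,
        learning_rate: float = 1e-3,
        weight_decay: float = 0.0,
        augment: bool = False,
        clip_x0: float = 6.0,
        standardize: bool = True,
        random_state: int = 0,
    ):
        self.order = order
        self.n_timesteps = n_timesteps
        self.schedule_s = schedule_s
        self.beta_clip = beta_clip
        self.hidden_dims = hidden_dims
        self.n_levels = n_levels
        self.resblocks_per_level = resblocks_per_level
        self.attention_levels = attention_levels
        self.time_embed_dim = time_embed_dim
        self.use_mask = use_mask
        self.use_demographics = use_demographics
        self.n_steps = n_steps
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.augment = augment
        self.clip_x0 = clip_x0
        self.standardize = standardize
        self.random_state = random_state

    # -- internals -------------------------------------------------------
    def _conditions(self, arrays: dict) -> ConditionSet:
        return ConditionSet(
            mask=arrays["mask"] if self.use_mask else None,
            age=arrays["age"] if self.use_demographics else None,
            sex=arrays["sex"] if self.use_demographics else None,
        )

    def _denoise_fn(self):
        def fn(xt, t, conditions):
            return self.unet_.predict_v(xt, t, conditions)

        return fn

    # -- estimator API ----------------------------------------------------
    def fit(self, X: list, y=None):
        """Train on a cohort (list of SubjectRecords), normally healthy controls."""
        if len(X) == 0:
            raise ValueError("cannot fit on an empty cohort")
        arrays = cohort_arrays(X)
        feats = arrays["features"]
        if self.standardize:
            feats, stats = standardize_channels(feats)
        else:
            stats = ChannelStats(
                mean=np.zeros(feats.shape[2]), std=np.ones(feats.shape[2])
            )
        self.channel_stats_ = stats
        self.n_channels_ = feats.shape[2]
        self.ico_ = build_icosphere(self.order)
        if feats.shape[1] != self.ico_.n_vertices:
            raise ValueError("cohort vertex count does not match the configured order")

        self.schedule_ = cosine_schedule(
            self.n_timesteps, s=self.schedule_s, clip=self.beta_clip
        )
        config = DenoiserConfig(
            base_order=self.order,
            in_channels=self.n_channels_,
            out_channels=self.n_channels_,
            mask_channels=1,
            n_levels=self.n_levels,
            hidden_dims=tuple(self.hidden_dims),
            resblocks_per_level=self.resblocks_per_level,
            attention_levels=tuple(self.attention_levels),
            time_embed_dim=self.time_embed_dim,
            use_mask=self.use_mask,
            use_demographics=self.use_demographics,
        )
        self.unet_ = SphericalUNet(config, seed=self.random_state)
        rng = np.random.default_rng(self.random_state)
        perms = icosahedral_symmetries(self.ico_) if self.augment else None
        self.loss_history_ = train_denoiser(
            self.unet_,
            feats,
            self._conditions(arrays),
            self.schedule_,
            n_steps=self.n_steps,
            batch_size=self.batch_size,
            lr=self.learning_rate,
            weight_decay=self.weight_decay,
            augment_perms=perms,
            rng=rng,
        )
        return self

    def sample(self, conditions_subjects: list, rng=None) -> np.ndarray:
        """Draw one feature map from pure noise per conditioning subject.

        Returns standardized-space maps, shape (n_subjects, V, C).
        """
        check_is_fitted(self, "unet_")
        rng = np.random.default_rng(self.random_state) if rng is None else rng
        arrays = cohort_arrays(conditions_subjects)
        cond = self._conditions(arrays)
        shape = (len(conditions_subjects), self.ico_.n_vertices, self.n_channels_)
        x = rng.standard_normal(shape)
        return sample_chain(
            self._denoise_fn(), x, self.schedule_.T, cond, self.schedule_, rng,
            clip_x0=self.clip_x0,
        )

    def reconstruct(
        self,
        subjects: list,
        n_samples: int = 10,
        t_start: int | None = None,
        rng=None,
    ) -> np.ndarray:
        """Pseudo-healthy reconstructions: partial noising to ``t_start``
        (default T/2) then conditional denoising, ``n_samples`` per subject.

        Returns standardized-space maps, shape (n_samples, n_subjects, V, C).
        """
        check_is_fitted(self, "unet_")
        rng = np.random.default_rng(self.random_state) if rng is None else rng
        t_start = self.schedule_.T // 2 if t_start is None else t_start
        arrays = cohort_arrays(subjects)
        feats, _ = standardize_channels(arrays["features"], self.channel_stats_)

        # flatten (sample, subject) into one batch axis and run the chains in
        # cache-friendly chunks; the math is identical to per-sample loops
        n_sub = feats.shape[0]
        rows = np.tile(feats, (n_samples, 1, 1))
        rep = lambda a: None if a is None else np.tile(a, (n_samples,) + (1,) * (a.ndim - 1))
        cond_all = ConditionSet(
            mask=rep(arrays["mask"]) if self.use_mask else None,
            age=rep(arrays["age"]) if self.use_demographics else None,
            sex=rep(arrays["sex"]) if self.use_demographics else None,
        )
        if t_start == 0:
            return rows.reshape(n_samples, n_sub, *feats.shape[1:]).copy()
        out = np.empty_like(rows)
        fn = self._denoise_fn()
        chunk = 200
        for lo in range(0, rows.shape[0], chunk):
            hi = min(lo + chunk, rows.shape[0])
            cond_c = ConditionSet(
                mask=None if cond_all.mask is None else cond_all.mask[lo:hi],
                age=None if cond_all.age is None else cond_all.age[lo:hi],
                sex=None if cond_all.sex is None else cond_all.sex[lo:hi],
            )
            out[lo:hi] = partial_reconstruct(
                rows[lo:hi], t_start, fn, cond_c, 1, self.schedule_, rng,
                clip_x0=self.clip_x0,
            )[0]
        return out.reshape(n_samples, n_sub, *feats.shape[1:])

    def standardized_features(self, subjects: list) -> np.ndarray:
        check_is_fitted(self, "channel_stats_")
        feats, _ = standardize_channels(
            cohort_arrays(subjects)["features"], self.channel_stats_
        )
        return feats


class NormativeScorer(BaseEstimator, TransformerMixin):
    """Per-ROI abnormality z-scores against a personalized reference set.

    With ``reference="ddpm"`` the reference set is ``n_samples`` pseudo-healthy
    reconstructions of the subject from the supplied fitted
    :class:`ConditionalSurfaceDDPM`; with ``reference="template"`` it is the
    ``n_samples`` training-cohort subjects closest in age.  ``transform``
    returns an ``(n_subjects, n_rois)`` matrix of z-scores on the configured
    feature channel (0 = cortical thickness).
    """

    def __init__(
        self,
        model: ConditionalSurfaceDDPM | None = None,
        reference: str = "ddpm",
        n_samples: int = 10,
        t_start: int | None = None,
        channel: int = 0,
        ddof: int = 1,
        random_state: int = 0,
    ):
        self.model = model
        self.reference = reference
        self.n_samples = n_samples
        self.t_start = t_start
        self.channel = channel
        self.ddof = ddof
        self.random_state = random_state

    def fit(self, X: list, y=None):
        """Record the reference cohort (training controls) and parcellation."""
        if self.reference not in ("ddpm", "template"):
            raise ValueError("reference must be 'ddpm' or 'template'")
        if self.reference == "ddpm" and self.model is None:
            raise ValueError("ddpm reference requires a fitted model")
        if len(X) == 0:
            raise ValueError("empty reference cohort")
        parc = X[0].parcellation
        if parc is None:
            raise ValueError("subjects must carry a parcellation")
        self.parcellation_ = parc
        self.train_subjects_ = list(X)
        self.train_ages_ = np.array([s.age for s in X])
        return self

    def transform(self, X: list) -> np.ndarray:
        check_is_fitted(self, "parcellation_")
        rng = np.random.default_rng(self.random_state)
        z = np.empty((len(X), self.parcellation_.n_rois))
        if self.reference == "ddpm":
            recon = self.model.reconstruct(
                X, n_samples=self.n_samples, t_start=self.t_start, rng=rng
            )  # (N, B, V, C)
            feats = self.model.standardized_features(X)
            for b, sub in enumerate(X):
                table = abnormal_scores(
                    feats[b, :, self.channel],
                    recon[:, b, :, self.channel],
                    self.parcellation_,
                    subject_id=sub.subject_id,
                    ddof=self.ddof,
                )
                z[b] = table.z
        else:
            for b, sub in enumerate(X):
                idx = template_reference(self.train_ages_, sub.age, k=self.n_samples)
                refs = np.stack(
                    [self.train_subjects_[i].features[:, self.channel] for i in idx]
                )
                table = abnormal_scores(
                    sub.features[:, self.channel],
                    refs,
                    self.parcellation_,
                    subject_id=sub.subject_id,
                    ddof=self.ddof,
                )
                z[b] = table.z
        return z


def save_model(path, model: ConditionalSurfaceDDPM) -> None:
    """Serialize a fitted model (parameters + config) to a single .npz file."""
    import json

    check_is_fitted(model, "unet_")
    arrays = {f"param_{i:04d}": a for i, a in enumerate(model.unet_.state_arrays())}
    meta = {
        "estimator_params": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in model.get_params().items()
        },
        "channel_stats": model.channel_stats_.to_dict(),
        "n_channels": int(model.n_channels_),
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> ConditionalSurfaceDDPM:
    """Load a model saved by :func:`save_model`, ready for sampling/scoring."""
    import json

    from .denoiser import DenoiserConfig, SphericalUNet
    from .diffusion import cosine_schedule
    from .geometry import build_icosphere, icosahedral_symmetries
    from .io import ChannelStats

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = [data[k] for k in sorted(k for k in data.files if k.startswith("param_"))]
    params = meta["estimator_params"]
    for k in ("hidden_dims", "attention_levels"):
        params[k] = tuple(params[k])
    model = ConditionalSurfaceDDPM(**params)
    model.channel_stats_ = ChannelStats.from_dict(meta["channel_stats"])
    model.n_channels_ = meta["n_channels"]
    model.ico_ = build_icosphere(model.order)
    model.schedule_ = cosine_schedule(model.n_timesteps, s=model.schedule_s, clip=model.beta_clip)
    config = DenoiserConfig(
        base_order=model.order,
        in_channels=model.n_channels_,
        out_channels=model.n_channels_,
        mask_channels=1,
        n_levels=model.n_levels,
        hidden_dims=tuple(model.hidden_dims),
        resblocks_per_level=model.resblocks_per_level,
        attention_levels=tuple(model.attention_levels),
        time_embed_dim=model.time_embed_dim,
        use_mask=model.use_mask,
        use_demographics=model.use_demographics,
    )
    model.unet_ = SphericalUNet(config, seed=model.random_state)
    model.unet_.load_state_arrays(arrays)
    model.loss_history_ = []
    return model
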