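"""Model/Results interface over the full depth-of-anesthesia method.

:class:`DoaModel` owns the data preparation — noise-assisted MEMD filtering
of each session's EEG, windowed sample entropy, lagged feature assembly and
the session-level split — and :meth:`DoaModel.fit` trains the
backpropagation network, returning a :class:`DoaResults` that carries the
fitted weights, per-session predictions, the evaluation report and a
plain-text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import ann, evaluate, memd, sampen
from .io_formats import IndexSeries, SessionBundle

__all__ = ["DoaModel", "DoaResults"]


@dataclass
class DoaModel:
    """Depth-of-anesthesia index model over a cohort of sessions."""

    sessions: list[SessionBundle]
    split: ann.SplitSpec
    entropy_tracks: dict[str, sampen.EntropyTrack]
    features: dict[str, ann.FeatureMatrix]
    lag: int = 6

    @classmethod
    def from_sessions(
        cls,
        sessions: list[SessionBundle],
        sift_config: memd.SiftConfig | None = None,
        sampen_params: sampen.SampEnParams | None = None,
        lag: int = 6,
        imf_indices: tuple[int, ...] = (2, 3),
        split: ann.SplitSpec | None = None,
        split_proportions: tuple[int, int, int] = (30, 10, 24),
        filter_eeg: bool = True,
    ) -> "DoaModel":
        """Prepare a cohort: filter each EEG, compute the entropy track, and
        assemble lagged features aligned with the EACL target.

        ``filter_eeg=False`` skips the MEMD stage and computes entropy on
        the raw EEG (useful for ablation).
        """
        sift_config = sift_config or memd.SiftConfig()
        sampen_params = sampen_params or sampen.SampEnParams()
        entropy_tracks: dict[str, sampen.EntropyTrack] = {}
        features: dict[str, ann.FeatureMatrix] = {}
        for s in sessions:
            sig = s.eeg
            if filter_eeg:
                sig = memd.filter_signal(sig, sift_config, imf_indices)
            track = sampen.windowed_sampen(sig, sampen_params)
            entropy_tracks[s.session_id] = track
            fm = ann.build_features(track, s.eacl, lag)
            fm.session_id = s.session_id
            features[s.session_id] = fm
        if split is None:
            split = ann.proportional_split(
                [s.session_id for s in sessions], split_proportions
            )
        return cls(
            sessions=sessions,
            split=split,
            entropy_tracks=entropy_tracks,
            features=features,
            lag=lag,
        )

    def fit(self, config: ann.TrainConfig | None = None) -> "DoaResults":
        """Train the network on the training sessions with early stopping on
        the validation sessions."""
        config = config or ann.TrainConfig()
        mlp = ann.train(
            [self.features[sid] for sid in self.split.train],
            [self.features[sid] for sid in self.split.validation],
            config,
        )
        return DoaResults(model=self, mlp=mlp)


@dataclass
class DoaResults:
    """Fitted index: trained network plus evaluation helpers."""

    model: DoaModel
    mlp: ann.MLPModel
    _report: evaluate.EvalReport | None = field(default=None, repr=False)

    def predict(self, session_id: str) -> IndexSeries:
        """Predicted 0-100 index track for one prepared session."""
        return ann.predict(self.mlp, self.model.entropy_tracks[session_id])

    def predictions(self, session_ids: list[str] | None = None) -> dict[str, IndexSeries]:
        ids = session_ids if session_ids is not None else self.model.split.test
        return {sid: self.predict(sid) for sid in ids}

    def evaluate(
        self,
        session_ids: list[str] | None = None,
        threshold: float = evaluate.AWAKE_THRESHOLD,
        root_mse: bool = False,
    ) -> evaluate.EvalReport:
        """Per-session correlation, MSE and AUC on the test sessions (or an
        explicit list), with cohort mean +/- SD."""
        ids = session_ids if session_ids is not None else self.model.split.test
        preds = self.predictions(ids)
        chosen = [s for s in self.model.sessions if s.session_id in preds]
        report = evaluate.evaluate_cohort(chosen, preds, threshold, root_mse)
        if session_ids is None:
            self._report = report
        return report

    def summary(self) -> str:
        """Plain-text summary of the fit and test-set performance."""
        split = self.model.split
        lines = [
            "Depth-of-anesthesia index — backpropagation network fit",
            "=" * 56,
            f"sessions: {len(self.model.sessions)} "
            f"(train {len(split.train)} / val {len(split.validation)} / "
            f"test {len(split.test)})",
            f"features: lag {self.mlp.lag} x windowed SampEn; hidden units "
            f"{self.mlp.w2.size}",
            "",
        ]
        report = self._report or self.evaluate()
        lines.append("test-set performance (mean ± SD over sessions):")
        for metric, row in report.summary.iterrows():
            sd = "---" if np.isnan(row["sd"]) else f"{row['sd']:.3f}"
            if np.isnan(row["mean"]):
                continue
            lines.append(f"  {metric:<22s} {row['mean']:.3f} ± {sd}")
        return "\n".join(lines)

    def plot_session(self, session_id: str, ax=None):
        """Plot EACL, the BIS-like reference and the predicted index for one
        session (mirrors the single-surgery overview figure)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        session = next(
            s for s in self.model.sessions if s.session_id == session_id
        )
        ax.plot(session.eacl.times / 60, session.eacl.values, label="EACL", color="k")
        if session.bis_ref is not None:
            ax.plot(
                session.bis_ref.times / 60,
                session.bis_ref.values,
                label="BIS-like reference",
                color="tab:blue",
                alpha=0.7,
            )
        pred = self.predict(session_id)
        ax.plot(pred.times / 60, pred.values, label="SampEn via ANN", color="tab:red")
        ax.axhline(evaluate.AWAKE_THRESHOLD, ls="--", color="grey", lw=0.8)
        ax.set(xlabel="time (min)", ylabel="consciousness index", ylim=(0, 100))
        ax.legend(loc="lower left", fontsize=8)
        return ax
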