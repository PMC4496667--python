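"""The weighted ensemble similarity classifier.

:class:`WesClassifier` is a scikit-learn style estimator over labeled
(protein, ligand) pairs.  Fitting runs the full training cascade:

1. build each protein's ligand *ensemble* from the positive pairs;
2. weight every feature of both channels by statistical enrichment against
   the whole training ligand library (Fisher exact / Wilcoxon rank-sum,
   Benjamini-Hochberg, w = -log10(q) below q = 0.05) and select features;
3. scan the similarity cutoff S_cut over a 0.01-step grid, choosing the
   value that maximises the ROC AUC of the Z-scores on the training pairs;
4. calibrate the random-raw-score null: 50 random library ligands per
   protein give a null mean and sd, regressed linearly on ligand-set size;
5. convert raw scores to Z-scores and pick the highest-F1 Z threshold;
6. in hybrid mode, fit class-conditional 2-D Gaussian KDEs over
   (z_binary, z_continuous), form the Bayesian likelihood L and pick the
   highest-F1 threshold theta.

Training-pair scores used for the cutoff and threshold scans are
*self-excluded*: a positive pair's query ligand never contributes its own
identity similarity.  Leave-one-interaction-out scoring
(:meth:`WesClassifier.score_pairs_heldout`) additionally refits the held-out
protein's weights, feature selection and null-calibration point exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

from . import density, null as null_mod, weighting
from .evaluate import _as_pair_frame, f1_threshold_scan, roc_auc
from .similarity import (S_CUT_GRID, raw_score, raw_score_profile,
                         weighted_cosine_matrix, weighted_tanimoto_matrix)

__all__ = ["LigandLibrary", "ProteinEnsemble", "WesClassifier",
           "save_model", "load_model"]

FORMAT_VERSION = 1
CHANNELS = ("binary", "continuous")


class LigandLibrary:
    """The training ligand collection: ids plus both feature matrices.

    The continuous matrix is standardised per feature over the library and
    the standardisation parameters are kept so query molecules are scaled by
    the training moments.
    """

    def __init__(self, ids, fp_matrix, desc_matrix, std_params=None):
        from .chem import standardize

        self.ids = list(ids)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ligand ids in library")
        self.fp = np.asarray(fp_matrix, dtype=np.uint8)
        desc = np.asarray(desc_matrix, dtype=float)
        if std_params is None:
            self.desc, self.std_params = standardize(desc)
        else:
            self.desc = desc
            self.std_params = std_params
        if self.fp.shape[0] != len(self.ids) or self.desc.shape[0] != len(self.ids):
            raise ValueError("row counts of feature matrices must match the id list")
        self.index = {lid: i for i, lid in enumerate(self.ids)}

    @classmethod
    def from_benchmark(cls, bench) -> "LigandLibrary":
        return cls(bench.ligand_ids, bench.fp_matrix, bench.desc_matrix)

    @classmethod
    def from_records(cls, records, n_bits: int = 1024) -> "LigandLibrary":
        from .chem import compute_binary_features, compute_continuous_features

        fp = compute_binary_features(records, n_bits=n_bits)
        if all(r.desc is not None for r in records):
            desc_raw = np.vstack([np.asarray(r.desc, dtype=float) for r in records])
            lib = cls([r.ligand_id for r in records], fp, desc_raw)
        else:
            from .chem import _rdkit_descriptor_matrix, standardize

            M, names = _rdkit_descriptor_matrix(records)
            std, params = standardize(M, feature_names=names)
            lib = cls([r.ligand_id for r in records], fp, std, std_params=params)
        return lib


@dataclass
class ProteinEnsemble:
    """One protein's trained state: membership, weights, selections."""

    protein_id: str
    member_idx: np.ndarray                       # rows of the library
    weights: dict = field(default_factory=dict)   # channel -> full weight vector
    selected_idx: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)
    q_values: dict = field(default_factory=dict)
    null_sample_idx: np.ndarray | None = None

    @property
    def size(self) -> int:
        return int(self.member_idx.size)


def _sim_matrix(channel, Q, E, w, idx):
    if channel == "binary":
        return weighted_tanimoto_matrix(Q, E, w, idx)
    return weighted_cosine_matrix(Q, E, w, idx)


class WesClassifier(BaseEstimator, ClassifierMixin):
    """Weighted ensemble similarity classifier for drug-target pairs.

    Parameters
    ----------
    library : LigandLibrary
        Feature matrices for every ligand referenced by the pairs.
    channel : {"hybrid", "binary", "continuous"}
        Hybrid fuses both Z-scores through the KDE likelihood; the single
        channel modes threshold their own Z-score.
    q_threshold : float
        Enrichment significance cutoff; features with q at or above it get
        zero weight.
    m_features : int or None
        Retain the top-m weighted features per protein and channel; None
        keeps every feature with positive weight.
    s_cut : "auto", float, or {channel: float}
        Similarity cutoff; "auto" scans the 0.01-step grid for the best
        training ROC AUC.
    n_random : int
        Random-ligand draw size for the null calibration.
    bandwidth_rule : {"scott", "silverman"}
        KDE bandwidth rule for the hybrid likelihood.
    priors : "empirical" or "uniform"
        Class priors for the Bayesian fusion.
    random_state : int
        Seed for every stochastic component (null draws).
    """

    def __init__(self, library=None, channel="hybrid", q_threshold=0.05,
                 m_features=None, s_cut="auto", n_random=50, sigma_floor=1e-6,
                 bandwidth_rule="scott", priors="empirical", random_state=0):
        self.library = library
        self.channel = channel
        self.q_threshold = q_threshold
        self.m_features = m_features
        self.s_cut = s_cut
        self.n_random = n_random
        self.sigma_floor = sigma_floor
        self.bandwidth_rule = bandwidth_rule
        self.priors = priors
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------

    def _channels(self):
        return CHANNELS if self.channel == "hybrid" else (self.channel,)

    def _matrix(self, channel) -> np.ndarray:
        return self.library.fp if channel == "binary" else self.library.desc

    def _fit_protein_weights(self, member_idx) -> dict:
        """Enrichment weights + selection for one membership, both channels."""
        out = {}
        lib_n = len(self.library.ids)
        for ch in self._channels():
            M = self._matrix(ch)
            E = M[member_idx]
            if ch == "binary":
                k = E.sum(axis=0).astype(np.int64)  # unsigned k-1 would wrap
                p = stats.hypergeom.sf(k - 1, lib_n, self._lib_bit_counts,
                                       member_idx.size)
                p = np.where(self._lib_bit_counts == 0, 1.0, np.clip(p, 0, 1))
            else:
                rest = np.delete(M, member_idx, axis=0)
                p = weighting.continuous_feature_pvalues(E, rest)
            q = weighting.adjust_pvalues(p)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                w = weighting.compute_weights(q, self.q_threshold)
                m = self.m_features if self.m_features is not None else int((w > 0).sum())
                sel = weighting.select_features(w, max(m, 1)) if (w > 0).any() \
                    else np.array([], dtype=int)
            out[ch] = dict(p=p, q=q, w=w, sel=sel)
        return out

    def _pair_sims(self, channel, ens: ProteinEnsemble, query_rows,
                   exclude_member_row=None) -> list:
        """Similarity vectors of query library rows vs the ensemble members."""
        M = self._matrix(channel)
        members = ens.member_idx
        if exclude_member_row is not None:
            members = members[members != exclude_member_row]
        if members.size == 0 or ens.selected_idx[channel].size == 0:
            return [np.zeros(max(members.size, 0)) for _ in query_rows]
        S = _sim_matrix(channel, M[np.asarray(query_rows)], M[members],
                        ens.weights[channel], ens.selected_idx[channel])
        return list(S)

    def _null_sims(self, channel, ens: ProteinEnsemble, member_idx=None) -> np.ndarray:
        members = ens.member_idx if member_idx is None else member_idx
        M = self._matrix(channel)
        if members.size == 0 or ens.selected_idx[channel].size == 0:
            return np.zeros((self.n_random, max(members.size, 1)))
        return _sim_matrix(channel, M[ens.null_sample_idx], M[members],
                           ens.weights[channel], ens.selected_idx[channel])

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        if self.library is None:
            raise ValueError("a LigandLibrary must be supplied")
        if self.channel not in ("hybrid", "binary", "continuous"):
            raise ValueError(f"unknown channel {self.channel!r}")
        pairs = _as_pair_frame(X, y)
        labels = pairs["label"].to_numpy()
        if np.unique(labels).size < 2:
            raise ValueError("training pairs must contain both classes")
        unknown = set(pairs["ligand_id"]) - set(self.library.index)
        if unknown:
            raise ValueError(f"ligands missing from library: {sorted(unknown)[:5]}")
        self.classes_ = np.array([0, 1])
        self._lib_bit_counts = self.library.fp.sum(axis=0).astype(np.int64)

        # ensembles from the positive pairs (deduplicated, sorted -> order-free)
        self.ensembles_ = {}
        pos = pairs.loc[pairs["label"] == 1]
        for pid, grp in pos.groupby("protein_id"):
            rows = np.array(sorted({self.library.index[l] for l in grp["ligand_id"]}))
            ens = ProteinEnsemble(protein_id=pid, member_idx=rows)
            seed = null_mod.protein_seed(self.random_state, pid)
            ens.null_sample_idx = null_mod.sample_background_indices(
                len(self.library.ids), self.n_random, seed)
            fitted = self._fit_protein_weights(rows)
            for ch, d in fitted.items():
                ens.p_values[ch] = d["p"]
                ens.q_values[ch] = d["q"]
                ens.weights[ch] = d["w"]
                ens.selected_idx[ch] = d["sel"]
            self.ensembles_[pid] = ens

        # training-pair similarity vectors (self-excluded for positives)
        pair_rows = pairs["ligand_id"].map(self.library.index).to_numpy()
        sims = {ch: [] for ch in self._channels()}
        for ch in self._channels():
            by_prot = {}
            for pid, grp in pairs.groupby("protein_id"):
                if pid not in self.ensembles_:
                    raise ValueError(f"protein {pid!r} has no positive training pairs")
                ens = self.ensembles_[pid]
                S = self._pair_sims(ch, ens, pair_rows[grp.index.to_numpy()])
                for local, (gidx, row) in enumerate(zip(grp.index, S)):
                    qrow = pair_rows[gidx]
                    if labels[gidx] == 1 and qrow in set(ens.member_idx):
                        pos_in_members = np.where(ens.member_idx == qrow)[0]
                        row = np.delete(row, pos_in_members)
                    by_prot[gidx] = row
            sims[ch] = [by_prot[i] for i in range(len(pairs))]
        self._train_pair_sims = sims
        pair_sizes = pairs["protein_id"].map(
            {p: e.size for p, e in self.ensembles_.items()}).to_numpy(dtype=float)

        # null similarity matrices
        null_sims = {ch: {p: self._null_sims(ch, e)
                          for p, e in self.ensembles_.items()}
                     for ch in self._channels()}

        # S_cut selection and null calibration per channel
        self.s_cut_ = {}
        self.null_models_ = {}
        self.scan_auc_ = {}
        zcols = {}
        prot_order = sorted(self.ensembles_)
        sizes = np.array([self.ensembles_[p].size for p in prot_order], dtype=float)
        for ch in self._channels():
            # an ensemble with no significant feature carries no evidence for
            # this channel: its pairs get Z = 0 rather than a floored-sigma
            # artifact that would vary with set size alone
            informative = pairs["protein_id"].map(
                {p: e.selected_idx[ch].size > 0
                 for p, e in self.ensembles_.items()}).to_numpy(dtype=bool)
            s_cut_param = self.s_cut if not isinstance(self.s_cut, dict) \
                else self.s_cut.get(ch, "auto")
            if s_cut_param == "auto":
                null_prof = np.stack([
                    np.vstack([raw_score_profile(row) for row in null_sims[ch][p]])
                    for p in prot_order])                  # (P, n_random, G)
                mu_prof = null_prof.mean(axis=1)           # (P, G)
                sd_prof = null_prof.std(axis=1, ddof=1)
                pair_prof = np.vstack([raw_score_profile(s) for s in sims[ch]])
                aucs = self._scan_grid_auc(pair_prof, labels, pairs, pair_sizes,
                                           mu_prof, sd_prof, sizes, prot_order,
                                           informative)
                self.scan_auc_[ch] = aucs
                best = int(np.argmax(aucs))                # argmax: first = smallest
                self.s_cut_[ch] = float(S_CUT_GRID[best])
            else:
                self.s_cut_[ch] = float(s_cut_param)
            mus, sds = [], []
            for p in prot_order:
                nr = null_mod.sample_random_raw_scores(null_sims[ch][p],
                                                       self.s_cut_[ch])
                mus.append(nr.mean())
                sds.append(nr.std(ddof=1))
            self.null_models_[ch] = null_mod.fit_null(
                sizes, mus, sds, channel=ch,
                n_random=self.n_random, sigma_floor=self.sigma_floor,
                rng_seed=self.random_state)
            raws = np.array([raw_score(s, self.s_cut_[ch])[0] for s in sims[ch]])
            zcols[ch] = np.where(informative,
                                 self.null_models_[ch].z(raws, pair_sizes), 0.0)

        # thresholds and the hybrid fusion
        self.z_threshold_ = {}
        for ch in self._channels():
            self.z_threshold_[ch], _ = f1_threshold_scan(zcols[ch], labels)
        self.train_scores_ = pairs.assign(
            **{f"z_{ch}": zcols[ch] for ch in self._channels()})
        if self.channel == "hybrid":
            Z = np.column_stack([zcols["binary"], zcols["continuous"]])
            self._fit_fusion(Z, labels)
            self.train_scores_["likelihood"] = self._likelihood(Z)
        return self

    def _fit_fusion(self, Z, labels):
        self.kde_pos_ = density.fit_kde(Z[labels == 1], self.bandwidth_rule,
                                        class_label="binder")
        self.kde_neg_ = density.fit_kde(Z[labels == 0], self.bandwidth_rule,
                                        class_label="nonbinder")
        L = self._likelihood(Z)
        self.theta_, _ = density.choose_theta(L, labels)

    def _likelihood(self, Z) -> np.ndarray:
        pri = None if self.priors == "empirical" else (0.5, 0.5)
        return density.likelihood(Z, self.kde_pos_, self.kde_neg_, priors=pri)

    def _scan_grid_auc(self, pair_prof, labels, pairs, pair_sizes,
                       mu_prof, sd_prof, sizes, prot_order, informative):
        """ROC AUC of the Z-scores at every grid cutoff (vectorised)."""
        # regression coefficients at every cutoff in one polyfit call
        cmu = np.polyfit(sizes, mu_prof, 1)                # (2, G)
        csd = np.polyfit(sizes, sd_prof, 1)
        mu_hat = np.outer(pair_sizes, cmu[0]) + cmu[1]
        sd_hat = np.maximum(np.outer(pair_sizes, csd[0]) + csd[1], self.sigma_floor)
        Zg = (pair_prof - mu_hat) / sd_hat                 # (n_pairs, G)
        Zg[~informative, :] = 0.0
        return np.array([roc_auc(Zg[:, g], labels) for g in range(Zg.shape[1])])

    # -- scoring -----------------------------------------------------------

    def score_pairs(self, X) -> pd.DataFrame:
        """Full-model scores (raw, Z per channel; likelihood and call)."""
        self._check_fitted()
        pairs = _as_pair_frame(X)
        self._check_targets(pairs)
        out = pairs.copy()
        rows = pairs["ligand_id"].map(self.library.index).to_numpy()
        zs = {}
        for ch in self._channels():
            raws = np.empty(len(pairs))
            for pid, grp in pairs.groupby("protein_id"):
                ens = self.ensembles_[pid]
                S = self._pair_sims(ch, ens, rows[grp.index.to_numpy()])
                for gidx, srow in zip(grp.index, S):
                    raws[gidx] = raw_score(srow, self.s_cut_[ch])[0]
            size = pairs["protein_id"].map(
                {p: e.size for p, e in self.ensembles_.items()}).to_numpy(dtype=float)
            informative = pairs["protein_id"].map(
                {p: e.selected_idx[ch].size > 0
                 for p, e in self.ensembles_.items()}).to_numpy(dtype=bool)
            zs[ch] = np.where(informative, self.null_models_[ch].z(raws, size), 0.0)
            out[f"raw_{ch}"] = raws
            out[f"z_{ch}"] = zs[ch]
        if self.channel == "hybrid":
            Z = np.column_stack([zs["binary"], zs["continuous"]])
            out["likelihood"] = self._likelihood(Z)
            out["call"] = out["likelihood"] > self.theta_
        else:
            ch = self.channel
            out["call"] = out[f"z_{ch}"] > self.z_threshold_[ch]
        return out

    def score_pairs_heldout(self, pairs: pd.DataFrame,
                            refit_thresholds: bool = True) -> pd.DataFrame:
        """Leave-one-interaction-out scores for labeled pairs.

        A held-out positive is removed from its protein's ensemble; the
        protein's enrichment weights, feature selection and null-calibration
        point are refit exactly before scoring.  Cutoffs stay at the trained
        operating point; decision thresholds and the KDE fusion are
        re-selected on the pooled held-out scores when ``refit_thresholds``.
        """
        self._check_fitted()
        pairs = pairs.reset_index(drop=True)
        labels = pairs["label"].to_numpy()
        prot_order = sorted(self.ensembles_)
        sizes_full = np.array([self.ensembles_[p].size for p in prot_order],
                              dtype=float)
        # full-model null moments at the operating cutoffs
        base_moments = {}
        for ch in self._channels():
            mus, sds = [], []
            for p in prot_order:
                nr = null_mod.sample_random_raw_scores(
                    self._null_sims(ch, self.ensembles_[p]), self.s_cut_[ch])
                mus.append(nr.mean())
                sds.append(nr.std(ddof=1))
            base_moments[ch] = (np.array(mus), np.array(sds))

        zcols = {ch: np.empty(len(pairs)) for ch in self._channels()}
        flags = np.zeros(len(pairs), dtype=bool)
        prot_pos = {p: i for i, p in enumerate(prot_order)}
        for i, row in pairs.iterrows():
            pid, lid, lab = row["protein_id"], row["ligand_id"], labels[i]
            ens = self.ensembles_[pid]
            qrow = self.library.index[lid]
            held_out = lab == 1 and qrow in set(ens.member_idx)
            if held_out:
                members = ens.member_idx[ens.member_idx != qrow]
                if members.size < 2:
                    warnings.warn(f"ensemble of {pid} reduced below 2 ligands "
                                  "by exclusion; scored with a degenerate set")
                    flags[i] = True
                red = ProteinEnsemble(protein_id=pid, member_idx=members,
                                      null_sample_idx=ens.null_sample_idx)
                fitted = self._fit_protein_weights(members)
                for ch, d in fitted.items():
                    red.weights[ch] = d["w"]
                    red.selected_idx[ch] = d["sel"]
                for ch in self._channels():
                    if red.selected_idx[ch].size == 0:
                        zcols[ch][i] = 0.0
                        continue
                    nm = self._refit_null(ch, base_moments[ch], sizes_full,
                                          prot_pos[pid], red)
                    sims = self._pair_sims(ch, red, [qrow])[0]
                    raw = raw_score(sims, self.s_cut_[ch])[0]
                    zcols[ch][i] = nm.z(raw, members.size)
            else:
                for ch in self._channels():
                    if ens.selected_idx[ch].size == 0:
                        zcols[ch][i] = 0.0
                        continue
                    nm = self.null_models_[ch]
                    sims = self._pair_sims(ch, ens, [qrow])[0]
                    raw = raw_score(sims, self.s_cut_[ch])[0]
                    zcols[ch][i] = nm.z(raw, ens.size)

        out = pairs.assign(**{f"z_{ch}": zcols[ch] for ch in self._channels()},
                           degenerate=flags)
        if refit_thresholds:
            thresholds = {}
            for ch in self._channels():
                thresholds[ch], _ = f1_threshold_scan(zcols[ch], labels)
                out[f"call_{ch}"] = zcols[ch] > thresholds[ch]
            self.heldout_z_threshold_ = thresholds
            if self.channel == "hybrid":
                Z = np.column_stack([zcols["binary"], zcols["continuous"]])
                kde_p = density.fit_kde(Z[labels == 1], self.bandwidth_rule,
                                        class_label="binder")
                kde_n = density.fit_kde(Z[labels == 0], self.bandwidth_rule,
                                        class_label="nonbinder")
                pri = None if self.priors == "empirical" else (0.5, 0.5)
                L = density.likelihood(Z, kde_p, kde_n, priors=pri)
                theta, _ = density.choose_theta(L, labels)
                out["likelihood"] = L
                out["call"] = L > theta
                self.heldout_theta_ = theta
                self.heldout_kde_pos_ = kde_p
                self.heldout_kde_neg_ = kde_n
            else:
                out["call"] = out[f"call_{self.channel}"]
        return out

    def _refit_null(self, ch, base, sizes_full, pidx, reduced_ens):
        """Null regression with one protein's moment point replaced."""
        mus, sds = (b.copy() for b in base)
        nr = null_mod.sample_random_raw_scores(
            self._null_sims(ch, reduced_ens), self.s_cut_[ch])
        mus[pidx] = nr.mean()
        sds[pidx] = nr.std(ddof=1)
        sizes = sizes_full.copy()
        sizes[pidx] = reduced_ens.size
        return null_mod.fit_null(sizes, mus, sds, channel=ch,
                                 n_random=self.n_random,
                                 sigma_floor=self.sigma_floor,
                                 rng_seed=self.random_state)

    # -- sklearn surface ---------------------------------------------------

    def predict(self, X) -> np.ndarray:
        return self.score_pairs(X)["call"].to_numpy().astype(int)

    def decision_function(self, X) -> np.ndarray:
        scored = self.score_pairs(X)
        if self.channel == "hybrid":
            return scored["likelihood"].to_numpy()
        return scored[f"z_{self.channel}"].to_numpy()

    def predict_proba(self, X) -> np.ndarray:
        if self.channel != "hybrid":
            raise AttributeError("predict_proba is defined for the hybrid model")
        L = self.score_pairs(X)["likelihood"].to_numpy()
        return np.column_stack([1 - L, L])

    def predict_targets(self, ligand_ids, targets=None) -> pd.DataFrame:
        """Score query ligands against targets, ranked per query."""
        self._check_fitted()
        if targets is None:
            targets = sorted(self.ensembles_)
        targets = list(targets)
        if not targets:
            return pd.DataFrame(columns=["protein_id", "ligand_id"])
        bad = [t for t in targets if t not in self.ensembles_]
        if bad:
            raise KeyError(f"unknown targets {bad}; valid: {sorted(self.ensembles_)}")
        X = pd.DataFrame([(t, l) for l in ligand_ids for t in targets],
                         columns=["protein_id", "ligand_id"])
        scored = self.score_pairs(X)
        key = "likelihood" if self.channel == "hybrid" else f"z_{self.channel}"
        return (scored.sort_values(["ligand_id", key], ascending=[True, False])
                .reset_index(drop=True))

    def _check_fitted(self):
        if not hasattr(self, "ensembles_"):
            raise RuntimeError("classifier is not fitted")

    def _check_targets(self, pairs):
        bad = sorted(set(pairs["protein_id"]) - set(self.ensembles_))
        if bad:
            raise KeyError(f"unknown targets {bad}; valid: {sorted(self.ensembles_)}")


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _arr(a):
    return np.asarray(a).tolist()


def save_model(model: WesClassifier, path) -> None:
    """Serialise a fitted classifier to a version-stamped JSON container."""
    model._check_fitted()
    lib = model.library
    ens_blocks = {}
    for pid, e in model.ensembles_.items():
        block = {"member_idx": _arr(e.member_idx),
                 "null_sample_idx": _arr(e.null_sample_idx),
                 "channels": {}}
        for ch in model._channels():
            w = e.weights[ch]
            nz = np.nonzero(w)[0]
            block["channels"][ch] = {
                "nonzero_idx": _arr(nz), "nonzero_w": _arr(w[nz]),
                "selected_idx": _arr(e.selected_idx[ch]),
                "n_features": int(w.size)}
        ens_blocks[pid] = block
    payload = {
        "format_version": FORMAT_VERSION,
        "params": {k: v for k, v in model.get_params().items() if k != "library"},
        "library": {
            "ids": lib.ids,
            "fp_packed": [np.packbits(r).tobytes().hex() for r in lib.fp],
            "n_bits": int(lib.fp.shape[1]),
            "desc": _arr(lib.desc),
            "std_mean": _arr(lib.std_params.mean),
            "std_sd": _arr(lib.std_params.sd),
            "std_kept": _arr(np.asarray(lib.std_params.kept, dtype=bool)),
        },
        "ensembles": ens_blocks,
        "s_cut": model.s_cut_,
        "null_models": {ch: {k: getattr(nm, k) for k in
                             ("channel", "alpha1", "beta1", "alpha2", "beta2",
                              "n_random", "sigma_floor", "r2_mu", "r2_sigma",
                              "rng_seed")}
                        for ch, nm in model.null_models_.items()},
        "z_threshold": model.z_threshold_,
    }
    if model.channel == "hybrid":
        payload["kde"] = {
            "pos": {"points": _arr(model.kde_pos_.points), "H": _arr(model.kde_pos_.H)},
            "neg": {"points": _arr(model.kde_neg_.points), "H": _arr(model.kde_neg_.H)},
            "theta": model.theta_,
        }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> WesClassifier:
    """Load a serialised classifier; refuses unknown format versions."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupted model file {path}: {exc}") from exc
    version = payload.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version!r}; "
                         f"this build reads version {FORMAT_VERSION}")
    libd = payload["library"]
    n_bits = libd["n_bits"]
    fp = np.vstack([np.unpackbits(np.frombuffer(bytes.fromhex(h), dtype=np.uint8))[:n_bits]
                    for h in libd["fp_packed"]])
    from .chem import StandardizationParams

    desc = np.asarray(libd["desc"], dtype=float)
    params = StandardizationParams(mean=np.asarray(libd["std_mean"], dtype=float),
                                   sd=np.asarray(libd["std_sd"], dtype=float),
                                   kept=np.asarray(libd["std_kept"], dtype=bool))
    lib = LigandLibrary(libd["ids"], fp, desc, std_params=params)
    model = WesClassifier(library=lib, **payload["params"])
    model.classes_ = np.array([0, 1])
    model._lib_bit_counts = lib.fp.sum(axis=0).astype(np.int64)
    model.ensembles_ = {}
    for pid, block in payload["ensembles"].items():
        e = ProteinEnsemble(protein_id=pid,
                            member_idx=np.asarray(block["member_idx"], dtype=int),
                            null_sample_idx=np.asarray(block["null_sample_idx"],
                                                       dtype=int))
        for ch, cd in block["channels"].items():
            w = np.zeros(cd["n_features"])
            w[np.asarray(cd["nonzero_idx"], dtype=int)] = cd["nonzero_w"]
            e.weights[ch] = w
            e.selected_idx[ch] = np.asarray(cd["selected_idx"], dtype=int)
        model.ensembles_[pid] = e
    model.s_cut_ = {k: float(v) for k, v in payload["s_cut"].items()}
    model.null_models_ = {ch: null_mod.NullModel(**d)
                          for ch, d in payload["null_models"].items()}
    model.z_threshold_ = {k: float(v) for k, v in payload["z_threshold"].items()}
    if "kde" in payload:
        model.kde_pos_ = density.KdeClassDensity(
            "binder", np.asarray(payload["kde"]["pos"]["points"]),
            np.asarray(payload["kde"]["pos"]["H"]))
        model.kde_neg_ = density.KdeClassDensity(
            "nonbinder", np.asarray(payload["kde"]["neg"]["points"]),
            np.asarray(payload["kde"]["neg"]["H"]))
        model.theta_ = float(payload["kde"]["theta"])
    return model
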