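"""Size-based rearrangement signatures, repair-mechanism inference, tandem
duplicator phenotype (TDP) scoring and genome-instability grouping.

Rearrangement sizes in tumor genomes are multi-modal on a log scale; a
Gaussian mixture fitted to log10(size) per SV class (TD, DEL, INV) yields
signature components (e.g. TD-c1 < TD-c2 < TD-c3 ordered by mode).  The
repair mechanism of an individual junction is indexed by its microhomology
and untemplated-insertion lengths.  A genome's TDP score measures how
unevenly its tandem duplications distribute over chromosomes relative to a
length-proportional expectation:

    TDPscore = - sum_i |Obs_i - Exp_i| / TD,    Exp_i = TD * L_i / sum(L)

which lies in [-2, 0]; 0 means a perfectly length-proportional spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .records import SVRecord

SV_CLASS_OF_TYPE = {
    "td_type": "TD",
    "deletion_type": "DEL",
    "head_to_head": "INV",
    "tail_to_tail": "INV",
}

MECHANISMS = ("NAHR", "alt_EJ", "NHEJ", "FoSTeS_MMBIR")


@dataclass
class SizeMixtureModel:
    """Per-class log10-size Gaussian mixture; components ordered by mean."""

    sv_class: str
    weights: np.ndarray
    means: np.ndarray  # log10 bp
    sds: np.ndarray    # log10 bp
    bic: float = float("nan")

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        order = np.argsort(self.means)
        self.weights = self.weights[order]
        self.means = self.means[order]
        self.sds = self.sds[order]
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.sds <= 0):
            raise ValueError("mixture sds must be positive")

    @property
    def k(self) -> int:
        return len(self.weights)

    @property
    def labels(self) -> list[str]:
        return [f"{self.sv_class}-c{j + 1}" for j in range(self.k)]

    @property
    def component_medians_bp(self) -> np.ndarray:
        """10**mean per component (the mode/median size in bp)."""
        return 10.0 ** self.means

    def posteriors(self, sizes) -> np.ndarray:
        """Posterior responsibility matrix (n, k) for sizes in bp."""
        x = np.log10(np.asarray(sizes, dtype=float)).reshape(-1, 1)
        dens = self.weights * norm.pdf(x, loc=self.means, scale=self.sds)
        total = dens.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        return dens / total


def fit_size_gmm(
    sizes,
    sv_class: str,
    k: int | None = None,
    seed: int = 0,
    k_range: tuple[int, int] = (1, 5),
    n_init: int = 20,
) -> SizeMixtureModel:
    """Fit a 1-D Gaussian mixture to log10(sizes).

    ``k=None`` selects the component count in ``k_range`` by BIC.  EM uses
    ``n_init`` random restarts and is deterministic given ``seed``.
    Requires at least 50 positive sizes.
    """
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size < 50:
        raise ValueError(f"need >=50 sizes to fit a mixture, got {sizes.size}")
    if np.any(sizes <= 0):
        raise ValueError("all sizes must be positive")
    x = np.log10(sizes).reshape(-1, 1)

    def _fit(kk: int) -> GaussianMixture:
        return GaussianMixture(
            n_components=kk,
            covariance_type="full",
            n_init=n_init,
            random_state=seed,
        ).fit(x)

    if k is not None:
        gm = _fit(k)
    else:
        best = None
        for kk in range(k_range[0], k_range[1] + 1):
            cand = _fit(kk)
            if best is None or cand.bic(x) < best.bic(x):
                best = cand
        gm = best
    return SizeMixtureModel(
        sv_class=sv_class,
        weights=gm.weights_,
        means=gm.means_.ravel(),
        sds=np.sqrt(gm.covariances_.ravel()),
        bic=float(gm.bic(x)),
    )


def assign_signature(sv: SVRecord, model: SizeMixtureModel) -> str:
    """Maximum-posterior component label for one SV (ties -> smaller index).

    The SV's type family must match the model's class; translocations have
    no size and are rejected.
    """
    family = SV_CLASS_OF_TYPE.get(sv.svtype)
    if family is None:
        raise ValueError(f"{sv.id}: translocations have no size signature")
    if family != model.sv_class:
        raise ValueError(
            f"{sv.id}: svtype {sv.svtype} ({family}) does not match "
            f"model class {model.sv_class}"
        )
    post = model.posteriors([max(sv.size, 1)])[0]
    j = int(np.argmax(post))  # argmax returns the first (smallest) index on ties
    return model.labels[j]


def infer_repair_mechanism(mh_len: int, ins_len: int) -> str:
    """Repair-mechanism label from microhomology/insertion lengths (bp).

    Rule order: insertion > 10 bp -> FoSTeS/MMBIR (template switching);
    microhomology > 100 bp -> NAHR; 2-100 bp -> alt-EJ; otherwise
    (0-1 bp microhomology or 1-10 bp insertion) -> NHEJ.
    """
    if mh_len < 0 or ins_len < 0:
        raise ValueError("mh_len/ins_len must be non-negative")
    if ins_len > 10:
        return "FoSTeS_MMBIR"
    if mh_len > 100:
        return "NAHR"
    if 2 <= mh_len <= 100:
        return "alt_EJ"
    return "NHEJ"


@dataclass
class MechanismCall:
    sv_id: str
    mechanism: str


def call_mechanisms(svs) -> list[MechanismCall]:
    return [MechanismCall(r.id, infer_repair_mechanism(r.mh_len, r.ins_len)) for r in svs]


# ---------------------------------------------------------------------------
# TDP

@dataclass
class TDPResult:
    sample: str
    td_total: int
    obs: dict[str, int]
    exp: dict[str, float]
    tdp_score: float
    is_tdp: bool | None = None


def compute_tdp(tds, chrom_lengths: dict[str, int], sample: str = "") -> TDPResult:
    """Score one genome's tandem-duplication chromosomal spread.

    ``tds`` is either a sequence of td_type SVRecords or a mapping
    chromosome -> observed TD count.  Expected counts are proportional to
    chromosome length.  A genome with zero TDs has an undefined score.
    """
    if isinstance(tds, dict):
        obs = {c: int(n) for c, n in tds.items()}
    else:
        obs = {}
        for r in tds:
            if r.svtype != "td_type":
                continue
            obs[r.bp1.chrom] = obs.get(r.bp1.chrom, 0) + 1
            if not sample and r.sample:
                sample = r.sample
    td_total = sum(obs.values())
    if td_total == 0:
        raise ValueError("TDP score is undefined for a genome with zero TDs")
    total_len = float(sum(chrom_lengths.values()))
    exp = {c: td_total * L / total_len for c, L in chrom_lengths.items()}
    dev = sum(abs(obs.get(c, 0) - exp[c]) for c in chrom_lengths)
    # chromosomes absent from the length table contribute their full count
    dev += sum(n for c, n in obs.items() if c not in chrom_lengths)
    score = -dev / td_total
    return TDPResult(sample=sample, td_total=td_total, obs=obs, exp=exp, tdp_score=score)


def call_tdp_status(
    results: list[TDPResult], cutoff: float | None = None, seed: int = 0
) -> list[TDPResult]:
    """Flag TDP genomes across a cohort.

    With an explicit ``cutoff``, ``is_tdp = score > cutoff``.  Otherwise the
    scores are split into two clusters (k-means, k=2, seeded) and the
    higher-score cluster is flagged; this requires >=10 samples and
    non-degenerate scores.
    """
    if cutoff is not None:
        for r in results:
            r.is_tdp = r.tdp_score > cutoff
        return results
    if len(results) < 10:
        raise ValueError("need >=10 samples for a data-driven TDP cutoff")
    scores = np.array([r.tdp_score for r in results]).reshape(-1, 1)
    if np.allclose(scores, scores[0]):
        raise ValueError("degenerate all-equal TDP scores; supply a cutoff")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(scores)
    high = int(np.argmax(km.cluster_centers_.ravel()))
    for r, lab in zip(results, km.labels_):
        r.is_tdp = bool(lab == high)
    return results


# ---------------------------------------------------------------------------
# instability grouping

@dataclass
class InstabilityCall:
    sample: str
    simple_sv_burden: int
    group: str  # stable | unstable


def classify_instability(burdens: dict[str, int]) -> list[InstabilityCall]:
    """Split a cohort at the median simple-SV burden: above -> unstable,
    at or below -> stable.  Requires >=2 samples."""
    if len(burdens) < 2:
        raise ValueError("need >=2 samples to split at the cohort median")
    med = float(np.median(list(burdens.values())))
    return [
        InstabilityCall(s, n, "unstable" if n > med else "stable")
        for s, n in burdens.items()
    ]
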