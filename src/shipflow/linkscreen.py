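"""Link screening: decide which origin-destination connections are plausible.

The fully connected network contains every ordered port pair; only a small
fraction correspond to real shipping connections. A binary classifier is
trained on distance features (great-circle and sea-route) and optionally on
edge importance -- the ratio of min-max-normalised trip weight to normalised
great-circle distance -- to separate real from pseudo links. The retained
pairs restrict the candidate destinations the gravity flow model allocates to.

Class balance is restored by stratified subsampling of the pseudo links
(strata = distance decile x source region) so that the sample preserves the
spatial distribution of the candidate pairs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .geo import GeoPoint, haversine
from .network import ShippingNetwork

logger = logging.getLogger(__name__)

DEFAULT_DETOUR_FACTOR = 1.15
CLASSIFIER_MENU = ("logistic", "kneighbors", "decision_tree", "gradient_boosting", "random_forest")

RouteProvider = Callable[[GeoPoint, GeoPoint], float]


@dataclass(frozen=True)
class SeaRouteDistance:
    """A sea-route distance in km; ``routed`` is False when the detour-factor
    fallback produced the value instead of an actual route provider."""

    km: float
    routed: bool


def searoute_distance(
    a: GeoPoint,
    b: GeoPoint,
    provider: RouteProvider | None = None,
    detour_factor: float = DEFAULT_DETOUR_FACTOR,
) -> SeaRouteDistance:
    """Sea-route distance between two points.

    With a provider, returns the routed distance (never below the great-circle
    distance); without one, approximates it as haversine x detour_factor.
    Provider failures fall back with a logged warning.
    """
    d_geo = haversine(a, b)
    if provider is not None:
        try:
            routed = float(provider(a, b))
            return SeaRouteDistance(max(routed, d_geo), routed=True)
        except Exception as exc:  # pragma: no cover - provider-dependent
            logger.warning("route provider failed (%s); using detour-factor fallback", exc)
    return SeaRouteDistance(d_geo * detour_factor, routed=False)


def edge_importance(net: ShippingNetwork, eps: float = 1e-6) -> dict[tuple[str, str], float]:
    """Edge importance I_ij = w-hat / (d-hat + eps) over all edges of the fully
    connected network, where w-hat and d-hat are min-max-normalised edge
    weights and great-circle distances. High-flow, short links score highest.
    """
    if not net.augmented:
        raise ValueError("edge importance is defined on the fully connected network")
    edges = list(net.graph.edges(data=True))
    ids, dmat = net.distance_matrix()
    index = {p: k for k, p in enumerate(ids)}
    w = np.array([float(d["w"]) for _, _, d in edges])
    dist = np.array([dmat[index[u], index[v]] for u, v, _ in edges])

    def _minmax(x: np.ndarray, what: str) -> np.ndarray:
        span = x.max() - x.min()
        if span <= 0:
            warnings.warn(f"all {what} equal; normalised values set to 0")
            return np.zeros_like(x)
        return (x - x.min()) / span

    importance = _minmax(w, "edge weights") / (_minmax(dist, "distances") + eps)
    return {(u, v): float(i) for (u, v, _), i in zip(edges, importance)}


def build_edge_features(
    net: ShippingNetwork,
    eps: float = 1e-6,
    provider: RouteProvider | None = None,
    detour_factor: float = DEFAULT_DETOUR_FACTOR,
    searoute_km: dict[tuple[str, str], float] | None = None,
) -> pd.DataFrame:
    """Feature rows for every edge of the fully connected network.

    Columns: source, dest, d_haversine, d_searoute, edge_importance, label
    (``real``/``pseudo``), source_region. Pre-computed sea-route distances can
    be supplied via ``searoute_km``; otherwise the provider/fallback is used.
    """
    imp = edge_importance(net, eps=eps)
    ids, dmat = net.distance_matrix()
    index = {p: k for k, p in enumerate(ids)}
    rows = []
    for u, v, data in net.graph.edges(data=True):
        d_h = dmat[index[u], index[v]]
        if searoute_km is not None and (u, v) in searoute_km:
            d_s = searoute_km[(u, v)]
        else:
            d_s = searoute_distance(
                net.ports[u].location, net.ports[v].location, provider, detour_factor
            ).km
        port = net.ports[u]
        rows.append(
            {
                "source": u,
                "dest": v,
                "d_haversine": d_h,
                "d_searoute": d_s,
                "edge_importance": imp[(u, v)],
                "label": "pseudo" if data.get("pseudo", False) else "real",
                "source_region": port.region or port.country,
            }
        )
    return pd.DataFrame(rows)


def sample_pseudo_links(rows: pd.DataFrame, seed: int, n_deciles: int = 10) -> pd.DataFrame:
    """Balance classes by stratified subsampling of the pseudo links.

    All real rows are kept. Pseudo rows are drawn without replacement from
    strata keyed by (haversine-distance decile, source region), each stratum
    contributing in proportion to its size (largest-remainder rounding).
    Strata that run short borrow from the nearest distance decile in the same
    region, then from the global pool. Deterministic under ``seed``.
    """
    real = rows[rows["label"] == "real"]
    pseudo = rows[rows["label"] == "pseudo"]
    if real.empty or pseudo.empty:
        raise ValueError("both real and pseudo rows are required for balancing")
    n_target = len(real)
    if len(pseudo) <= n_target:
        return pd.concat([real, pseudo], ignore_index=True)

    rng = np.random.default_rng(seed)
    pseudo = pseudo.copy()
    # Distance deciles computed over the pseudo rows themselves.
    deciles = pd.qcut(pseudo["d_haversine"].rank(method="first"), n_deciles, labels=False)
    pseudo["_dec"] = deciles.astype(int)
    region_col = pseudo["source_region"] if "source_region" in pseudo else pd.Series("all", index=pseudo.index)
    pseudo["_region"] = region_col

    groups = {k: idx for k, idx in pseudo.groupby(["_dec", "_region"]).groups.items()}
    keys = sorted(groups)
    sizes = np.array([len(groups[k]) for k in keys])
    quota = n_target * sizes / sizes.sum()
    take = np.floor(quota).astype(int)
    remainder = quota - take
    short = n_target - take.sum()
    for k in np.argsort(-remainder)[:short]:
        take[k] += 1

    chosen: list = []
    deficits: list[tuple[tuple, int]] = []
    for k, n_take in zip(keys, take):
        idx = np.array(sorted(groups[k]))
        if n_take >= len(idx):
            chosen.extend(idx.tolist())
            if n_take > len(idx):
                deficits.append((k, n_take - len(idx)))
        elif n_take > 0:
            chosen.extend(rng.choice(idx, size=n_take, replace=False).tolist())
    chosen_set = set(chosen)
    for (dec, region), deficit in deficits:
        logger.info("stratum (%s, %s) short by %d pseudo rows; borrowing", dec, region, deficit)
        # Prefer neighbouring deciles within the same region, nearest first.
        candidates = pseudo.index.difference(chosen_set)
        cand = pseudo.loc[candidates]
        same_region = cand[cand["_region"] == region]
        order = (same_region["_dec"] - dec).abs().sort_values(kind="stable")
        borrow = order.index[:deficit].tolist()
        if len(borrow) < deficit:
            others = cand.index.difference(borrow)
            borrow += rng.choice(np.array(sorted(others)), size=deficit - len(borrow),
                                 replace=False).tolist()
        chosen_set.update(borrow)
        chosen.extend(borrow)
    balanced = pd.concat(
        [real, pseudo.loc[sorted(chosen_set)].drop(columns=["_dec", "_region"])],
        ignore_index=True,
    )
    return balanced


@dataclass
class ScreenConfig:
    """Configuration of the link-screening stage."""

    classifier_menu: Sequence[str] = CLASSIFIER_MENU
    use_edge_importance: bool = True
    train_fraction: float = 0.75
    cv_folds: int = 5
    seed: int = 0
    #: which fitted model becomes the deployed filter; None selects logistic
    #: when on the menu (it prunes unstable 1-2-trip links), else the model
    #: with the best validation accuracy.
    filter_model: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        unknown = set(self.classifier_menu) - set(CLASSIFIER_MENU)
        if unknown:
            raise ValueError(f"unknown classifiers: {sorted(unknown)}")

    def feature_columns(self) -> list[str]:
        cols = ["d_haversine", "d_searoute"]
        if self.use_edge_importance:
            cols.append("edge_importance")
        return cols


def _model_grid(name: str, seed: int):
    """Fixed, small grid-search spaces; ties resolved by first-listed set."""
    if name == "logistic":
        est = Pipeline([("scale", StandardScaler()),
                        ("clf", LogisticRegression(max_iter=2000, random_state=seed))])
        grid = {"clf__C": [1.0, 0.1, 10.0]}
    elif name == "kneighbors":
        est = Pipeline([("scale", StandardScaler()), ("clf", KNeighborsClassifier())])
        grid = {"clf__n_neighbors": [5, 3, 9]}
    elif name == "decision_tree":
        est = DecisionTreeClassifier(random_state=seed)
        grid = {"max_depth": [5, 3, None]}
    elif name == "gradient_boosting":
        est = GradientBoostingClassifier(random_state=seed)
        grid = {"n_estimators": [50], "max_depth": [3, 2]}
    elif name == "random_forest":
        est = RandomForestClassifier(random_state=seed)
        grid = {"n_estimators": [100], "max_depth": [None, 8]}
    else:
        raise ValueError(f"unknown classifier {name!r}")
    return est, grid


@dataclass
class LinkScreen:
    """A fitted link filter: the deployed model plus its feature columns."""

    model: object
    feature_columns: list[str]
    name: str
    report: pd.DataFrame = field(repr=False, default=None)

    def predict_real(self, features: pd.DataFrame) -> np.ndarray:
        return self.model.predict(features[self.feature_columns].to_numpy()) == 1


def train_link_classifier(
    rows: pd.DataFrame,
    cfg: ScreenConfig,
    test_rows: pd.DataFrame | None = None,
) -> tuple[LinkScreen, pd.DataFrame]:
    """Grid-search every menu classifier and report validation/test accuracy.

    ``rows`` should be class-balanced (see :func:`sample_pseudo_links`); they
    are split train_fraction/(1-train_fraction) with stratification, each
    model is tuned with cv_folds-fold grid-search cross-validation on the
    training part, and plain accuracy is reported on the held-out validation
    part and on ``test_rows`` when given. The deployed filter model is
    returned with the report.
    """
    labels = rows["label"].to_numpy()
    if len(set(labels)) < 2:
        raise ValueError("training rows contain a single class")
    cols = cfg.feature_columns()
    X = rows[cols].to_numpy()
    y = (labels == "real").astype(int)
    X_tr, X_val, y_tr, y_val = train_test_split(
        X, y, train_size=cfg.train_fraction, stratify=y, random_state=cfg.seed
    )
    records = []
    fitted = {}
    for name in cfg.classifier_menu:
        est, grid = _model_grid(name, cfg.seed)
        search = GridSearchCV(est, grid, cv=cfg.cv_folds, scoring="accuracy")
        search.fit(X_tr, y_tr)
        best = search.best_estimator_
        rec = {
            "model": name,
            "cv_accuracy": float(search.best_score_),
            "validation_accuracy": float(best.score(X_val, y_val)),
        }
        if test_rows is not None:
            rec["test_accuracy"] = float(
                best.score(test_rows[cols].to_numpy(), (test_rows["label"] == "real").astype(int))
            )
        records.append(rec)
        fitted[name] = best
    report = pd.DataFrame(records).set_index("model")
    if cfg.filter_model is not None:
        selected = cfg.filter_model
    elif "logistic" in fitted:
        selected = "logistic"
    else:
        selected = report["validation_accuracy"].idxmax()
    screen = LinkScreen(fitted[selected], cols, selected, report)
    return screen, report


def screen_links(
    net: ShippingNetwork,
    screen: LinkScreen,
    features: pd.DataFrame | None = None,
) -> set[tuple[str, str]]:
    """Score every ordered pair of the fully connected network and return the
    pairs classified as real connections."""
    if features is None:
        features = build_edge_features(net)
    keep = screen.predict_real(features)
    return {
        (s, d) for s, d, k in zip(features["source"], features["dest"], keep) if k
    }
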