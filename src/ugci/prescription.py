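"""Prescription step: ternary decomposition of low-index grids.

Grids rated ``low`` or ``extremely_low`` are decomposed over the three
highest-weight components: with normalized values ``(a, b, c)`` the ternary
coordinates are ``X = a/(a+b+c)`` etc.  A point near a vertex means that
component is relatively strong and the *other two* are the limited ones;
a point near the centre means all three are uniformly low.  Each diagnosed
grid is matched to a management strategy from an editable lookup table
keyed by land-cover class and limited component(s).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator

from .grids import GridRaster
from .index import IndexResult, NormalizedMatrix, WeightVector, select_top_components

__all__ = [
    "TernaryCoordinates",
    "CATEGORY_VERTEX",
    "CATEGORY_CENTER",
    "CATEGORY_INTERMEDIATE",
    "TernaryLimitationClassifier",
    "ternary_coordinates",
    "diagnose",
    "load_strategies",
    "recommend",
    "prescribe",
    "plot_ternary",
]

CATEGORY_VERTEX = "vertex_dominant"
CATEGORY_CENTER = "center"
CATEGORY_INTERMEDIATE = "intermediate"

_CENTER = np.array([1.0, 1.0, 1.0]) / 3.0


@dataclass
class TernaryCoordinates:
    """Per-grid simplex coordinates over the three selected components.

    ``defined`` is False where all three inputs were zero (a fully depleted
    grid has no direction on the simplex); coordinates are NaN there.
    """

    xyz: np.ndarray  # (n, 3); rows sum to 1 where defined
    defined: np.ndarray  # (n,) bool
    component_names: tuple[str, str, str]


def ternary_coordinates(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    component_names: tuple[str, str, str] = ("a", "b", "c"),
) -> TernaryCoordinates:
    """Relative proportions ``(X, Y, Z) = (a, b, c) / (a + b + c)``.

    Inputs are min-max-normalized component values in [0, 1]; a grid with
    ``a = b = c = 0`` is reported undefined rather than placed on the plot.
    """
    abc = np.column_stack([np.asarray(a, dtype=float).ravel(),
                           np.asarray(b, dtype=float).ravel(),
                           np.asarray(c, dtype=float).ravel()])
    if np.any((abc < 0) | (abc > 1)):
        raise ValueError("ternary inputs must be normalized values in [0, 1]")
    totals = abc.sum(axis=1)
    defined = totals > 0
    xyz = np.full_like(abc, np.nan)
    xyz[defined] = abc[defined] / totals[defined, None]
    return TernaryCoordinates(xyz=xyz, defined=defined,
                              component_names=component_names)


def diagnose(
    coords: TernaryCoordinates,
    vertex_threshold: float = 0.5,
    center_radius: float = 0.15,
    limited_threshold: float = 0.15,
) -> pd.DataFrame:
    """Categorize each defined ternary point.

    A point whose largest proportion reaches ``vertex_threshold`` is
    vertex-dominant: the dominant component is relatively strong and the
    other two are flagged limited.  A point within Euclidean distance
    ``center_radius`` of (1/3, 1/3, 1/3) is ``center``: all three
    components are uniformly low.  Everything else is ``intermediate``;
    there, components whose proportion falls to ``limited_threshold`` or
    below (points near a ternary edge, e.g. one component several-fold
    weaker than the other two) are flagged limited.  Vertex dominance is
    checked first; ties on the maximum go to the first component in the
    selected order.
    """
    if not coords.defined.all():
        raise ValueError("diagnose requires defined coordinates; filter undefined grids first")
    xyz = coords.xyz
    names = list(coords.component_names)
    max_idx = np.argmax(xyz, axis=1)
    max_val = xyz[np.arange(len(xyz)), max_idx]
    dist = np.linalg.norm(xyz - _CENTER, axis=1)
    category = np.where(
        max_val >= vertex_threshold,
        CATEGORY_VERTEX,
        np.where(dist <= center_radius, CATEGORY_CENTER, CATEGORY_INTERMEDIATE),
    )
    dominant = np.where(category == CATEGORY_VERTEX,
                        np.asarray(names, dtype=object)[max_idx], None)
    limited = []
    for row, cat, mi in zip(xyz, category, max_idx):
        if cat == CATEGORY_VERTEX:
            limited.append(tuple(nm for j, nm in enumerate(names) if j != mi))
        elif cat == CATEGORY_CENTER:
            limited.append(tuple(names))
        else:
            limited.append(tuple(nm for j, nm in enumerate(names)
                                 if row[j] <= limited_threshold))
    return pd.DataFrame({
        "category": category,
        "dominant_component": dominant,
        "limited_components": limited,
        "center_distance": dist,
    })


class TernaryLimitationClassifier(BaseEstimator):
    """Scikit-learn wrapper around the ternary limitation rule.

    Stateless (``fit`` is a no-op); ``predict`` maps an (n, 3) array of
    simplex coordinates to category labels using the configured
    ``vertex_threshold`` and ``center_radius``.
    """

    def __init__(self, vertex_threshold: float = 0.5, center_radius: float = 0.15):
        self.vertex_threshold = vertex_threshold
        self.center_radius = center_radius

    def fit(self, X=None, y=None):
        return self

    def predict(self, X) -> np.ndarray:
        xyz = np.asarray(X, dtype=float)
        coords = TernaryCoordinates(
            xyz=xyz, defined=np.ones(len(xyz), dtype=bool),
            component_names=("a", "b", "c"),
        )
        return diagnose(coords, self.vertex_threshold, self.center_radius)[
            "category"
        ].to_numpy()


def load_strategies(path: str | Path | None = None) -> dict:
    """Load the management-strategy table (packaged default or a user file)."""
    if path is None:
        text = resources.files("ugci").joinpath("strategies.yaml").read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)


def recommend(
    landcover_class: str,
    limited_components: tuple[str, ...],
    category: str,
    strategies: dict | None = None,
) -> str:
    """Strategy text for one diagnosed grid.

    Center grids get the class's ``all`` bundle; grids with specific
    limited components get those components' entries concatenated; grids
    without a specific limitation fall back to the class's ``general``
    entry.
    """
    if strategies is None:
        strategies = load_strategies()
    if landcover_class not in strategies:
        raise KeyError(
            f"no strategies configured for land-cover class {landcover_class!r}"
        )
    table = strategies[landcover_class]
    if category == CATEGORY_CENTER:
        return table["all"]
    parts = [table[c] for c in limited_components if c in table]
    if parts:
        return " ".join(parts)
    return table.get("general", table["all"])


def prescribe(
    index: IndexResult,
    norm: NormalizedMatrix,
    weights: WeightVector,
    landcover: GridRaster,
    valid_indices: np.ndarray,
    class_names: dict[int, str],
    vertex_threshold: float = 0.5,
    center_radius: float = 0.15,
    limited_threshold: float = 0.15,
    strategies: dict | None = None,
) -> pd.DataFrame:
    """Per-grid limitation diagnoses for the low and extremely-low grids.

    Rows cover exactly the ``low``/``extremely_low`` grids whose ternary
    coordinates are defined (grids with all selected components at zero are
    fully depleted and omitted).  ``valid_indices`` maps matrix rows back to
    raster (row, col) positions; classes without a configured strategy get
    an empty strategy string.
    """
    if strategies is None:
        strategies = load_strategies()
    top = select_top_components(weights, count=3)
    names = tuple(norm.component_names[j] for j in top)
    low = index.levels <= 1  # extremely_low (0) or low (1)
    if not low.any():
        return _empty_prescription()
    sub = norm.values[np.ix_(np.flatnonzero(low), top)]
    coords = ternary_coordinates(sub[:, 0], sub[:, 1], sub[:, 2],
                                 component_names=names)
    rows_rc = valid_indices[low]
    keep = coords.defined
    xyz = coords.xyz[keep]
    rows_rc = rows_rc[keep]
    ugci_vals = index.ugci[low][keep]
    level_codes = index.levels[low][keep]
    diag = diagnose(
        TernaryCoordinates(xyz=xyz, defined=np.ones(len(xyz), dtype=bool),
                           component_names=names),
        vertex_threshold, center_radius, limited_threshold,
    )
    lc_codes = landcover.values[rows_rc[:, 0], rows_rc[:, 1]]
    lc_names = [class_names.get(int(code), str(int(code))) for code in lc_codes]
    strategy_texts = []
    for cls, cat, lim in zip(lc_names, diag["category"], diag["limited_components"]):
        try:
            strategy_texts.append(recommend(cls, tuple(lim), cat, strategies))
        except KeyError:
            strategy_texts.append("")
    from .index import MANAGEMENT_LEVELS

    return pd.DataFrame({
        "row": rows_rc[:, 0],
        "col": rows_rc[:, 1],
        "landcover": lc_names,
        "level": np.asarray(MANAGEMENT_LEVELS, dtype=object)[level_codes],
        "ugci": ugci_vals,
        "x": xyz[:, 0],
        "y": xyz[:, 1],
        "z": xyz[:, 2],
        "category": diag["category"].to_numpy(),
        "dominant_component": diag["dominant_component"].to_numpy(),
        "limited_components": ["+".join(t) for t in diag["limited_components"]],
        "strategy": strategy_texts,
    })


def _empty_prescription() -> pd.DataFrame:
    return pd.DataFrame(columns=[
        "row", "col", "landcover", "level", "ugci", "x", "y", "z",
        "category", "dominant_component", "limited_components", "strategy",
    ])


def plot_ternary(table: pd.DataFrame, component_names, ax=None, title=None):
    """Scatter the prescription table on a ternary plot (one axes).

    Points are colored by management level (extremely-low vs low), matching
    the per-class panel layout of the diagnosis figures.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.5))
    corners = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
    tri = np.vstack([corners, corners[0]])
    ax.plot(tri[:, 0], tri[:, 1], color="0.3", lw=1)
    colors = {"extremely_low": "tab:blue", "low": "tab:red"}
    for level, group in table.groupby("level"):
        xyz = group[["x", "y", "z"]].to_numpy()
        pts = xyz @ corners
        ax.scatter(pts[:, 0], pts[:, 1], s=8, alpha=0.6,
                   color=colors.get(level, "0.5"), label=str(level))
    offsets = [(-0.03, -0.04), (0.03, -0.04), (0.0, 0.04)]
    for name, corner, off in zip(component_names, corners, offsets):
        ax.annotate(name, corner + off, ha="center", fontsize=8)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title, fontsize=10)
    if len(table):
        ax.legend(fontsize=7, loc="upper right")
    return ax
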