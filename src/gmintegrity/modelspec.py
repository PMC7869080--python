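"""Declarative latent-variable model specifications.

A :class:`ModelSpec` lists observed and latent variables, directed paths
(loadings and regressions), and variance/covariance terms.  Each term is
either *fixed* to a numeric value or *free* with a label; shared labels mean
equality constraints.  The mean structure is saturated by default: every
observed variable gets a free mean, latent means are fixed at zero.

A small text syntax in the lavaan style is supported for convenience::

    F =~ x1 + x2 + x3        # loadings; first indicator fixed to 1
    F =~ NA*x1 + x2          # free the first loading instead
    y ~ F + 0.5*x            # regressions (fixed value via premultiplier)
    F ~~ G                   # covariance
    x1 ~~ 0*x1               # fix a (residual) variance
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import yaml


@dataclass
class Path:
    """Directed edge ``src -> dst`` (loading or regression coefficient)."""

    src: str
    dst: str
    label: str | None = None   # free parameter label (None if fixed)
    value: float | None = None  # fixed value (None if free)
    start: float | None = None  # optional start value / sign hint

    def __post_init__(self) -> None:
        if (self.label is None) == (self.value is None):
            raise ValueError(f"path {self.src}->{self.dst}: exactly one of label/value")


@dataclass
class Cov:
    """Symmetric term: variance if ``a == b``, covariance otherwise."""

    a: str
    b: str
    label: str | None = None
    value: float | None = None
    start: float | None = None

    def __post_init__(self) -> None:
        if (self.label is None) == (self.value is None):
            raise ValueError(f"cov {self.a}~~{self.b}: exactly one of label/value")

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.a, self.b)))


@dataclass
class ModelSpec:
    """A latent-variable model over named variables."""

    observed: list[str]
    latents: list[str] = field(default_factory=list)
    paths: list[Path] = field(default_factory=list)
    covs: list[Cov] = field(default_factory=list)
    #: optional mean overrides: var -> label (free) or float (fixed)
    means: dict = field(default_factory=dict)
    group_var: str | None = None

    # -- construction helpers ---------------------------------------------
    def add_loading(self, factor: str, indicator: str, *, fixed: float | None = None,
                    label: str | None = None, start: float | None = None) -> None:
        if fixed is None and label is None:
            label = f"l_{factor}_{indicator}"
        self.paths.append(Path(factor, indicator, label=label, value=fixed, start=start))

    def add_regression(self, outcome: str, predictor: str, *, fixed: float | None = None,
                       label: str | None = None, start: float | None = None) -> None:
        if fixed is None and label is None:
            label = f"b_{outcome}_{predictor}"
        self.paths.append(Path(predictor, outcome, label=label, value=fixed, start=start))

    def add_cov(self, a: str, b: str, *, fixed: float | None = None,
                label: str | None = None, start: float | None = None) -> None:
        if fixed is None and label is None:
            label = f"v_{a}" if a == b else f"c_{a}_{b}"
        self.covs.append(Cov(a, b, label=label, value=fixed, start=start))

    # -- bookkeeping -------------------------------------------------------
    @property
    def variables(self) -> list[str]:
        return list(self.observed) + list(self.latents)

    def free_structure_labels(self) -> list[str]:
        """Unique labels of free covariance-structure parameters (no means)."""
        seen: list[str] = []
        for term in list(self.paths) + list(self.covs):
            if term.label is not None and term.label not in seen:
                seen.append(term.label)
        return seen

    def mean_term(self, var: str):
        """Label or fixed value of the mean of ``var``."""
        if var in self.means:
            return self.means[var]
        return f"mu_{var}" if var in self.observed else 0.0

    def validate(self) -> None:
        names = set(self.variables)
        if len(names) != len(self.variables):
            raise ValueError("duplicate variable names")
        for p in self.paths:
            if p.src not in names or p.dst not in names:
                raise ValueError(f"unknown variable in path {p.src}->{p.dst}")
        for c in self.covs:
            if c.a not in names or c.b not in names:
                raise ValueError(f"unknown variable in cov {c.a}~~{c.b}")
        keys = [(p.src, p.dst) for p in self.paths]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate directed edges")
        ckeys = [c.key for c in self.covs]
        if len(ckeys) != len(set(ckeys)):
            raise ValueError("duplicate variance/covariance terms")
        self._check_identification()
        self._check_acyclic()

    def _check_identification(self) -> None:
        for lat in self.latents:
            fixed_loading = any(p.src == lat and p.value is not None and p.value != 0.0
                                for p in self.paths)
            fixed_var = any(c.a == lat and c.b == lat and c.value is not None
                            for c in self.covs)
            if not (fixed_loading or fixed_var):
                raise ValueError(
                    f"latent {lat!r} is unidentified: fix a loading or its variance")

    def _check_acyclic(self) -> None:
        adj: dict[str, list[str]] = {}
        for p in self.paths:
            adj.setdefault(p.src, []).append(p.dst)
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {v: WHITE for v in self.variables}

        def visit(v: str) -> None:
            color[v] = GRAY
            for w in adj.get(v, ()):
                if color[w] == GRAY:
                    raise ValueError(f"cyclic directed paths involving {w!r}")
                if color[w] == WHITE:
                    visit(w)
            color[v] = BLACK

        for v in self.variables:
            if color[v] == WHITE:
                visit(v)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def term(t):
            d = {"label": t.label} if t.label is not None else {"value": t.value}
            if t.start is not None:
                d["start"] = t.start
            return d

        return {
            "observed": list(self.observed),
            "latents": list(self.latents),
            "paths": [{"src": p.src, "dst": p.dst, **term(p)} for p in self.paths],
            "covs": [{"a": c.a, "b": c.b, **term(c)} for c in self.covs],
            "means": dict(self.means),
            "group_var": self.group_var,
        }

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        spec = cls(observed=list(d["observed"]), latents=list(d.get("latents", [])),
                   means=dict(d.get("means", {})), group_var=d.get("group_var"))
        for p in d.get("paths", []):
            spec.paths.append(Path(p["src"], p["dst"], label=p.get("label"),
                                   value=p.get("value"), start=p.get("start")))
        for c in d.get("covs", []):
            spec.covs.append(Cov(c["a"], c["b"], label=c.get("label"),
                                 value=c.get("value"), start=c.get("start")))
        return spec

    @classmethod
    def from_yaml(cls, text_or_path) -> "ModelSpec":
        text = text_or_path
        try:
            with open(text_or_path) as fh:
                text = fh.read()
        except (OSError, TypeError):
            pass
        return cls.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# lavaan-style text parser
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^(?:(NA|[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?)\*)?([A-Za-z_][\w.]*)$")


def _parse_terms(rhs: str):
    out = []
    for raw in rhs.split("+"):
        m = _TERM_RE.match(raw.strip())
        if not m:
            raise ValueError(f"cannot parse model term {raw.strip()!r}")
        mult, name = m.groups()
        if mult is None:
            out.append((name, None))
        elif mult == "NA":
            out.append((name, "free"))
        else:
            out.append((name, float(mult)))
    return out


def parse_model(text: str, observed: list[str] | None = None) -> ModelSpec:
    """Build a :class:`ModelSpec` from lavaan-style model text.

    Latents are the left-hand sides of ``=~`` lines; every other variable is
    observed (their order can be pinned with ``observed``).  The first
    indicator of each factor is fixed to 1 unless prefixed with ``NA*``.
    Variance/covariance terms not given explicitly are added as free
    parameters for every variable, plus free covariances declared via ``~~``.
    """
    latents: list[str] = []
    loadings: list[tuple[str, str, object]] = []
    regressions: list[tuple[str, str, object]] = []
    covs: list[tuple[str, str, object]] = []

    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=~" in line:
            lhs, rhs = [s.strip() for s in line.split("=~", 1)]
            if lhs not in latents:
                latents.append(lhs)
            terms = _parse_terms(rhs)
            for i, (name, mult) in enumerate(terms):
                if mult is None:
                    mult = 1.0 if i == 0 else "free"
                loadings.append((lhs, name, mult))
        elif "~~" in line:
            lhs, rhs = [s.strip() for s in line.split("~~", 1)]
            for name, mult in _parse_terms(rhs):
                covs.append((lhs, name, "free" if mult is None else mult))
        elif "~" in line:
            lhs, rhs = [s.strip() for s in line.split("~", 1)]
            for name, mult in _parse_terms(rhs):
                regressions.append((lhs, name, "free" if mult is None else mult))
        else:
            raise ValueError(f"cannot parse model line {line!r}")

    mentioned: list[str] = []
    for src, dst, _ in loadings + [(a, b, None) for a, b, _ in covs]:
        for v in (src, dst):
            if v not in latents and v not in mentioned:
                mentioned.append(v)
    for dst, src, _ in regressions:
        for v in (dst, src):
            if v not in latents and v not in mentioned:
                mentioned.append(v)
    obs = observed if observed is not None else mentioned
    spec = ModelSpec(observed=list(obs), latents=latents)
    for fac, ind, mult in loadings:
        if mult == "free":
            spec.add_loading(fac, ind)
        else:
            spec.add_loading(fac, ind, fixed=float(mult))
    for dst, src, mult in regressions:
        if mult == "free":
            spec.add_regression(dst, src)
        else:
            spec.add_regression(dst, src, fixed=float(mult))
    explicit = set()
    for a, b, mult in covs:
        explicit.add(tuple(sorted((a, b))))
        if mult == "free":
            spec.add_cov(a, b)
        else:
            spec.add_cov(a, b, fixed=float(mult))
    # free variances for every variable not given explicitly
    for v in spec.variables:
        if (v, v) not in explicit:
            spec.add_cov(v, v)
    spec.validate()
    return spec
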