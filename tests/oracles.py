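"""Independent oracles used by the test suite.

Everything here is deliberately brute-force and shares no code path with
the implementations it checks.
"""

import numpy as np
from scipy import optimize, special


def haversine_m(lon1, lat1, lon2, lat2, radius):
    """Great-circle distance on a sphere of the given radius (metres)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dl = np.radians(lon2 - lon1)
    dp = p2 - p1
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return 2 * radius * np.arcsin(np.sqrt(a))


def vincenty_m(lon1, lat1, lon2, lat2, a=6_378_137.0, f=1 / 298.257223563):
    """WGS84 geodesic (inverse Vincenty) distance in metres."""
    b = a * (1 - f)
    u1 = np.arctan((1 - f) * np.tan(np.radians(lat1)))
    u2 = np.arctan((1 - f) * np.tan(np.radians(lat2)))
    ll = np.radians(lon2 - lon1)
    lam = ll
    for _ in range(200):
        s_sig = np.sqrt(
            (np.cos(u2) * np.sin(lam)) ** 2
            + (np.cos(u1) * np.sin(u2) - np.sin(u1) * np.cos(u2) * np.cos(lam)) ** 2
        )
        if s_sig == 0:
            return 0.0
        c_sig = np.sin(u1) * np.sin(u2) + np.cos(u1) * np.cos(u2) * np.cos(lam)
        sig = np.arctan2(s_sig, c_sig)
        sin_alpha = np.cos(u1) * np.cos(u2) * np.sin(lam) / s_sig
        cos2_alpha = 1 - sin_alpha**2
        cos_2sigm = c_sig - 2 * np.sin(u1) * np.sin(u2) / cos2_alpha if cos2_alpha else 0.0
        c = f / 16 * cos2_alpha * (4 + f * (4 - 3 * cos2_alpha))
        lam_new = ll + (1 - c) * f * sin_alpha * (
            sig + c * s_sig * (cos_2sigm + c * c_sig * (-1 + 2 * cos_2sigm**2))
        )
        if abs(lam_new - lam) < 1e-13:
            lam = lam_new
            break
        lam = lam_new
    u_sq = cos2_alpha * (a**2 - b**2) / b**2
    big_a = 1 + u_sq / 16384 * (4096 + u_sq * (-768 + u_sq * (320 - 175 * u_sq)))
    big_b = u_sq / 1024 * (256 + u_sq * (-128 + u_sq * (74 - 47 * u_sq)))
    d_sig = big_b * s_sig * (
        cos_2sigm
        + big_b / 4 * (
            c_sig * (-1 + 2 * cos_2sigm**2)
            - big_b / 6 * cos_2sigm * (-3 + 4 * s_sig**2) * (-3 + 4 * cos_2sigm**2)
        )
    )
    return float(b * big_a * (sig - d_sig))


def brute_mean_pairwise(coords):
    """O(N^2) double-loop mean pairwise distance."""
    n = len(coords)
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += float(np.hypot(coords[i][0] - coords[j][0], coords[i][1] - coords[j][1]))
    return total / (n * (n - 1) / 2)


def brute_per_point_dispersion(coords, divisor="n_minus_1"):
    """Direct transcription of the per-point averaging definition."""
    n = len(coords)
    per_point = []
    for i in range(n):
        s = sum(
            float(np.hypot(coords[i][0] - coords[j][0], coords[i][1] - coords[j][1]))
            for j in range(n) if j != i
        )
        per_point.append(s / (n - 1 if divisor == "n_minus_1" else n))
    return float(np.mean(per_point))


def monte_carlo_area_ha(poly, n_samples, seed):
    """Rejection-sampling polygon area: bounding-box hit fraction."""
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = poly.shapely.bounds
    xs = rng.uniform(minx, maxx, n_samples)
    ys = rng.uniform(miny, maxy, n_samples)
    import shapely

    hits = shapely.contains_xy(poly.shapely, xs, ys).sum()
    box_area = (maxx - minx) * (maxy - miny)
    return hits / n_samples * box_area / 10_000.0


def brute_hull_vertices(coords):
    """O(n^4)-flavour hull: a point is interior iff inside some triangle
    of three other points; hull vertices are the rest."""
    pts = np.asarray(coords, dtype=float)
    n = len(pts)

    def cross2(u, v):
        return u[0] * v[1] - u[1] * v[0]

    def in_triangle(p, a, b, c):
        d1 = cross2(b - a, p - a)
        d2 = cross2(c - b, p - b)
        d3 = cross2(a - c, p - c)
        has_neg = (d1 < -1e-12) or (d2 < -1e-12) or (d3 < -1e-12)
        has_pos = (d1 > 1e-12) or (d2 > 1e-12) or (d3 > 1e-12)
        return not (has_neg and has_pos)

    hull = []
    for i in range(n):
        interior = False
        others = [j for j in range(n) if j != i]
        for ai in range(len(others)):
            for bi in range(ai + 1, len(others)):
                for ci in range(bi + 1, len(others)):
                    a, b, c = pts[others[ai]], pts[others[bi]], pts[others[ci]]
                    if abs(cross2(b - a, c - a)) < 1e-12:
                        continue
                    if in_triangle(pts[i], a, b, c):
                        interior = True
                        break
                if interior:
                    break
            if interior:
                break
        if not interior:
            hull.append(tuple(pts[i]))
    return set(hull)


def gamma_loglik(y, mu, shape):
    """Direct Gamma log-density sum, mean/shape parameterization."""
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    return float(
        np.sum(
            shape * np.log(shape) - special.gammaln(shape) + (shape - 1) * np.log(y)
            - shape * np.log(mu) - shape * y / mu
        )
    )


def direct_ml_gamma_glm(y, X):
    """IRLS-free Gamma log-link ML: maximize the log density directly over
    (beta, log shape) with analytic gradients."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    p = X.shape[1]

    def negll_grad(theta):
        beta, la = theta[:p], theta[p]
        a = np.exp(la)
        eta = X @ beta
        mu = np.exp(eta)
        ll = np.sum(
            a * la - special.gammaln(a) + (a - 1) * np.log(y) - a * eta - a * y / mu
        )
        gbeta = a * X.T @ (y / mu - 1.0)
        gla = a * np.sum(la + 1 - special.digamma(a) + np.log(y) - eta - y / mu)
        return -ll, -np.concatenate([gbeta, [gla]])

    beta0, *_ = np.linalg.lstsq(X, np.log(y), rcond=None)
    res = optimize.minimize(
        negll_grad, np.concatenate([beta0, [0.0]]), jac=True, method="BFGS",
        options={"gtol": 1e-12, "maxiter": 2000},
    )
    return res.x[:p], np.exp(res.x[p]), -res.fun


def gauss_hermite_glmm_loglik(y, X, Z, groups, beta, sigma, gamma, n_nodes=80):
    """Marginal Gamma random-intercept GLMM log-likelihood by plain
    Gauss-Hermite quadrature (independent of any Laplace code)."""
    y = np.asarray(y, float)
    eta0 = np.asarray(X, float) @ beta
    phi = np.exp(np.asarray(Z, float) @ gamma)
    shape = 1.0 / phi
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    b_vals = np.sqrt(2.0) * sigma * nodes
    total = 0.0
    for g in np.unique(groups):
        m = groups == g
        lls = np.array(
            [gamma_loglik(y[m], np.exp(eta0[m] + b), shape[m]) for b in b_vals]
        )
        mx = lls.max()
        total += mx + np.log(np.sum(weights * np.exp(lls - mx)) / np.sqrt(np.pi))
    return float(total)
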