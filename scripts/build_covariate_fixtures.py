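"""Regenerate the packaged synthetic covariate fixtures.

The original cohort's covariate distribution parameters are not available,
so the package ships synthetic stand-ins with ranges typical of an
extremely-preterm cohort (birthweight ~800 g, gestational age ~26.5 weeks).
This script writes the two fixture JSON files under src/twinclust/data/.

Run from the repository root:  python scripts/build_covariate_fixtures.py
"""

from pathlib import Path

import numpy as np

# cross-sibling correlations per continuous covariate: birthweight 0.7,
# gestational age 0.95 (twins share the pregnancy; 0.95 is the largest
# round value keeping the joint block positive-definite given the 0.55
# birthweight-gestation correlation within an infant), Apgar 0.3
CROSS_SIB = {"bweight": 0.70, "gestage": 0.95, "apgar": 0.30}


def cov_from(sds, corr):
    sds = np.asarray(sds, dtype=float)
    return np.outer(sds, sds) * np.asarray(corr, dtype=float)


def twin_block(singleton_cov, names):
    """Joint 2k covariance [[S, G], [G, S]] with G_mn = sqrt(c_m c_n) S_mn."""
    c = np.sqrt([CROSS_SIB[n] for n in names])
    gamma = singleton_cov * np.outer(c, c)
    top = np.hstack([singleton_cov, gamma])
    bottom = np.hstack([gamma, singleton_cov])
    pair = np.vstack([top, bottom])
    assert np.linalg.eigvalsh(pair).min() > 0, "twin covariance must be PD"
    return pair


def death_model():
    names = ["bweight", "gestage", "apgar"]
    corr = [[1.0, 0.55, 0.15], [0.55, 1.0, 0.20], [0.15, 0.20, 1.0]]
    cov_s = cov_from([160.0, 1.4, 2.0], corr)
    cov_t = twin_block(cov_s, names)
    means_s = {0: [810.0, 26.3, 7.0], 1: [860.0, 26.4, 6.8]}
    means_t = {0: [760.0, 26.2, 7.0], 1: [800.0, 26.3, 6.8]}
    mvn = {}
    for sex in (0, 1):
        mvn[f"sex={sex}"] = {
            "singleton": {"mean": means_s[sex], "cov": cov_s.tolist()},
            "twin_pair": {"mean": means_t[sex] * 2, "cov": cov_t.tolist()},
        }
    return {
        "_comment": (
            "Synthetic stand-in covariate distribution for a preterm cohort "
            "(death outcome model); not estimated from any real dataset."
        ),
        "continuous": names,
        "categorical": ["sex"],
        "profiles": [
            {"levels": {"sex": 0}, "prob_singleton": 0.45, "prob_twin": 0.45},
            {"levels": {"sex": 1}, "prob_singleton": 0.55, "prob_twin": 0.55},
        ],
        "mvn": mvn,
        "truncation": {"apgar": "apgar"},
    }


def o2dep_model():
    names = ["bweight", "gestage"]
    corr = [[1.0, 0.55], [0.55, 1.0]]
    cov_s = cov_from([160.0, 1.4], corr)
    cov_t = twin_block(cov_s, names)
    # means: male infants ~50 g heavier; maternal smoking -60 g, -0.1 wk;
    # twins ~50 g lighter than singletons
    mvn = {}
    profiles = []
    p_male, p_smoke = 0.55, 0.28
    for sex in (0, 1):
        for smoke in (0, 1):
            mean_s = [820.0 + 50.0 * sex - 60.0 * smoke, 26.4 + 0.1 * sex - 0.1 * smoke]
            mean_t = [mean_s[0] - 50.0, mean_s[1] - 0.1]
            label = f"sex={sex}|smoking={smoke}"
            mvn[label] = {
                "singleton": {"mean": mean_s, "cov": cov_s.tolist()},
                "twin_pair": {"mean": mean_t * 2, "cov": cov_t.tolist()},
            }
            prob = (p_male if sex else 1 - p_male) * (p_smoke if smoke else 1 - p_smoke)
            profiles.append(
                {
                    "levels": {"sex": sex, "smoking": smoke},
                    "prob_singleton": round(prob, 6),
                    "prob_twin": round(prob, 6),
                }
            )
    return {
        "_comment": (
            "Synthetic stand-in covariate distribution for a preterm cohort "
            "(oxygen-dependence outcome model); not estimated from any real dataset."
        ),
        "continuous": names,
        "categorical": ["sex", "smoking"],
        "profiles": profiles,
        "mvn": mvn,
        "truncation": {},
    }


def main():
    import json

    out = Path(__file__).resolve().parents[1] / "src" / "twinclust" / "data"
    out.mkdir(parents=True, exist_ok=True)
    for name, payload in (
        ("synthetic_ukos_death.json", death_model()),
        ("synthetic_ukos_o2dep.json", o2dep_model()),
    ):
        (out / name).write_text(json.dumps(payload, indent=1) + "\n")
        print("wrote", out / name)


if __name__ == "__main__":
    main()
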