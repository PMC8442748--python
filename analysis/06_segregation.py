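#!/usr/bin/env python
"""Mendelian segregation test on the simulated F2 phenotypes.

Checks that fertile : sterile counts fit the 3:1 ratio expected for a
single fully penetrant recessive gene (chi-square goodness of fit, df=1),
and shows how the class frequencies translate into the theoretical
delta-SNP-index threshold of 2/3.
"""

from pathlib import Path

from bsamap import io_formats, mendel, simdata
from bsamap.snp_index import theoretical_delta

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    result = simdata.simulate_case(simdata.SimConfig(), seed=SEED)
    pheno = result.population.phenotypes
    n_sterile = int((pheno == "sterile").sum())
    n_fertile = int((pheno == "fertile").sum())

    cross = mendel.CrossModel("F2_self", "recessive", penetrance=1.0)
    ratio = mendel.expected_ratio(cross)
    chi2, df, p = mendel.chi_square_gof((n_fertile, n_sterile), ratio)
    verdict = "consistent" if p > 0.05 else "NOT consistent"
    print(f"F2 phenotypes: {n_fertile} fertile : {n_sterile} sterile")
    print(f"chi-square vs {ratio[0]:.0f}:{ratio[1]:.0f} -> "
          f"chi2={chi2:.4f} (df={df}), p={p:.4g} ({verdict} with 3:1)")

    f_rec = mendel.expected_bulk_freq(cross, "recessive")
    f_dom = mendel.expected_bulk_freq(cross, "dominant")
    print(f"expected bulk allele frequencies: sterile {f_rec:.4f}, fertile {f_dom:.4f}")
    print(f"theoretical delta-SNP-index threshold: {theoretical_delta(cross):.3f}")

    out = RESULTS / "segregation"
    out.mkdir(parents=True, exist_ok=True)
    import pandas as pd

    io_formats.write_tsv(
        pd.DataFrame(
            [{"n_fertile": n_fertile, "n_sterile": n_sterile,
              "chi2": chi2, "df": df, "p": p}]
        ),
        out / "segregation_test.tsv",
        {"ratio": "3:1", "seed": SEED},
    )


if __name__ == "__main__":
    main()
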