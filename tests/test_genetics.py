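"""Genotype enumeration, gamete distributions and inheritance cubes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import semdrive as sd
from semdrive.errors import ConfigurationError, DomainError
from semdrive.genetics import FEMALE, MALE, canon, wild_genotype

from conftest import ALL_DESIGNS, ALL_FLAVORS, random_params

SIMPLE = sd.DesignSpec("CIS_AUTO", "SIMPLIFIED")
DP_FIG = sd.DriveParams(p=0.5, q=1.0)
SP_FIG = sd.SemParams(a=0.5, b=1.0, c=1.0)


# ---------------------------------------------------------------------------
# enumeration


@pytest.mark.parametrize(
    "design,flavor,sem_res,sex,expected",
    [
        ("CIS_AUTO", "SIMPLIFIED", False, FEMALE, 10),  # C(4+1,2) over {G,H,V,W}
        ("CIS_AUTO", "SIMPLIFIED", False, MALE, 10),
        ("CIS_X", "SIMPLIFIED", False, MALE, 4),  # hemizygous: allele x Y
        ("CIS_X", "SIMPLIFIED", False, FEMALE, 10),
        ("TRANS_AUTO_AUTO", "SIMPLIFIED", False, FEMALE, 30),  # 10 drive x 3 element
        ("TRANS_AUTO_X", "SIMPLIFIED", False, MALE, 12),  # 4 hemizygous drive x 3
        ("TRANS_X_AUTO", "SIMPLIFIED", False, MALE, 20),  # 10 drive x 2 hemizygous element
        ("CIS_AUTO", "SIMPLIFIED", True, FEMALE, 15),  # +S: C(5+1,2)
        ("CIS_AUTO", "REDUCED", False, FEMALE, 15),  # +R
        ("CIS_AUTO", "COMPLETE", False, FEMALE, 21),  # +R +B
    ],
)
def test_genotype_counts(design, flavor, sem_res, sex, expected):
    spec = sd.DesignSpec(design, flavor, sem_resistance=sem_res)
    genos = sd.enumerate_genotypes(spec, sex)
    assert len(genos) == expected
    labels = [g.label for g in genos]
    assert len(set(labels)) == len(labels), "duplicate genotypes"


def test_enumeration_stable_and_canonical():
    a = sd.enumerate_genotypes(SIMPLE, FEMALE)
    b = sd.enumerate_genotypes(SIMPLE, FEMALE)
    assert [g.label for g in a] == [g.label for g in b]
    for g in a:
        assert canon(canon(g)) == canon(g) == g


def test_unknown_design_and_flavor_rejected():
    with pytest.raises(ConfigurationError, match="design_id"):
        sd.DesignSpec("CIS_NOWHERE", "SIMPLIFIED")
    with pytest.raises(ConfigurationError, match="flavor"):
        sd.DesignSpec("CIS_AUTO", "FANCY")


def test_male_x_genotypes_carry_y_token():
    spec = sd.DesignSpec("CIS_X", "SIMPLIFIED")
    for g in sd.enumerate_genotypes(spec, MALE):
        assert g.label.endswith("Y")
        assert g.allele_counts()["W" if "W" in g.label else g.label[0]] >= 0
        assert "Y" not in g.allele_counts()


# ---------------------------------------------------------------------------
# gamete distributions


def test_drive_gamete_examples():
    gw = sd.Genotype((("G", "W"),), FEMALE)
    # cleavage 50%, HR 100%: converted half plus Mendelian half
    assert sd.drive_gamete_dist(gw, DP_FIG, SIMPLE) == {("G",): 0.75, ("W",): 0.25}
    ww = sd.Genotype((("W", "W"),), FEMALE)
    assert sd.drive_gamete_dist(ww, DP_FIG, SIMPLE) == {("W",): 1.0}
    # full cleavage, pure NHEJ: half drive, half lethal token
    d = sd.drive_gamete_dist(gw, sd.DriveParams(p=1.0, q=0.0), SIMPLE)
    assert d == {("G",): 0.5, ("B",): 0.5}


def test_homing_requires_active_partner_and_alphabet_check():
    vw = sd.Genotype((("V", "W"),), FEMALE)
    assert sd.drive_gamete_dist(vw, sd.DriveParams(p=1.0, q=1.0), SIMPLE) == {
        ("V",): 0.5,
        ("W",): 0.5,
    }
    with pytest.raises(DomainError):
        sd.drive_gamete_dist(
            sd.Genotype((("Z", "W"),), FEMALE), DP_FIG, SIMPLE
        )


def test_inducible_drive_suppressed_without_molecule():
    spec = sd.DesignSpec("CIS_AUTO", "SIMPLIFIED", inducible_drive=True)
    gw = sd.Genotype((("G", "W"),), FEMALE)
    off = sd.drive_gamete_dist(gw, DP_FIG, spec, molecule_present=False)
    assert off == {("G",): 0.5, ("W",): 0.5}
    on = sd.drive_gamete_dist(gw, DP_FIG, spec, molecule_present=True)
    assert on == {("G",): 0.75, ("W",): 0.25}


def test_sem_transform_examples():
    # activation splits G gametes by the excision-cleavage rate
    g = sd.Genotype((("G", "G"),), FEMALE)
    out = sd.sem_transform({("G",): 1.0}, g, SP_FIG, SIMPLE, molecule_present=True)
    assert out == {("G",): 0.5, ("H",): 0.5}
    # parental H with perfect SSA repair resolves entirely to V
    hh = sd.Genotype((("H", "H"),), FEMALE)
    assert sd.gamete_distribution(hh, DP_FIG, SP_FIG, SIMPLE, molecule_present=True) == {
        ("V",): 1.0
    }
    # identity when the inducer is absent
    assert sd.sem_transform({("G",): 1.0}, g, SP_FIG, SIMPLE, molecule_present=False) == {
        ("G",): 1.0
    }


def test_trans_design_requires_element_copy():
    spec = sd.DesignSpec("TRANS_AUTO_AUTO", "SIMPLIFIED")
    sp = sd.SemParams(a=1.0, b=1.0, c=1.0)
    no_e = sd.Genotype((("G", "G"), ("w", "w")), FEMALE)
    with_e = sd.Genotype((("G", "G"), ("E", "w")), FEMALE)
    d_no = sd.gamete_distribution(no_e, DP_FIG, sp, spec, molecule_present=True)
    assert all(gam[0] == "G" for gam in d_no)
    d_yes = sd.gamete_distribution(with_e, DP_FIG, sp, spec, molecule_present=True)
    assert all(gam[0] == "H" for gam in d_yes)


def test_sem_resistance_routes_nhej_to_s():
    spec = sd.DesignSpec("CIS_AUTO", "SIMPLIFIED", sem_resistance=True)
    hh = sd.Genotype((("H", "H"),), FEMALE)
    d = sd.gamete_distribution(
        hh, DP_FIG, sd.SemParams(a=0.5, b=0.4, c=0.75), spec, molecule_present=True
    )
    assert d[("S",)] == pytest.approx(0.6)
    assert d[("V",)] == pytest.approx(0.3)
    assert d[("W",)] == pytest.approx(0.1)


@pytest.mark.parametrize("design", ALL_DESIGNS)
@pytest.mark.parametrize("flavor", ALL_FLAVORS)
def test_gamete_mass_conserved_random_params(design, flavor, rng):
    spec = sd.DesignSpec(design, flavor, sem_resistance=bool(rng.integers(2)))
    for _ in range(20):
        dp, sp = random_params(rng)
        for sex in (FEMALE, MALE):
            for g in sd.enumerate_genotypes(spec, sex):
                d = sd.gamete_distribution(g, dp, sp, spec, bool(rng.integers(2)))
                assert abs(sum(d.values()) - 1.0) < 1e-12
                assert all(v >= 0 for v in d.values())


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    p=st.floats(0, 1), q=st.floats(0, 1), a=st.floats(0, 1), b=st.floats(0, 1), c=st.floats(0, 1)
)
def test_gamete_mass_property(p, q, a, b, c):
    dp, sp = sd.DriveParams(p=p, q=q), sd.SemParams(a=a, b=b, c=c)
    for g in sd.enumerate_genotypes(SIMPLE, FEMALE):
        d = sd.gamete_distribution(g, dp, sp, SIMPLE, molecule_present=True)
        assert abs(sum(d.values()) - 1.0) < 1e-12


def test_drive_share_monotone_in_p_and_q():
    gw = sd.Genotype((("G", "W"),), FEMALE)
    grid = np.linspace(0, 1, 6)
    for q in grid:
        shares = [
            sd.drive_gamete_dist(gw, sd.DriveParams(p=p, q=q), SIMPLE).get(("G",), 0.0)
            for p in grid
        ]
        assert all(b >= a - 1e-12 for a, b in zip(shares, shares[1:]))
    for p in grid:
        shares = [
            sd.drive_gamete_dist(gw, sd.DriveParams(p=p, q=q), SIMPLE).get(("G",), 0.0)
            for q in grid
        ]
        assert all(b >= a - 1e-12 for a, b in zip(shares, shares[1:]))


# ---------------------------------------------------------------------------
# cubes


def test_build_cube_examples(sem_release_build):
    cube = sem_release_build["cube_off"]
    # Mendelian identity of the wild cross
    row = cube.row("WW", "WW")
    assert row[cube.offspring_index["WW"]] == pytest.approx(1.0)
    assert row.sum() == pytest.approx(1.0)
    # drive heterozygote x wild female row
    row = cube.row("GW", "WW")
    assert row[cube.offspring_index["GW"]] == pytest.approx(0.75)
    assert row[cube.offspring_index["WW"]] == pytest.approx(0.25)


@pytest.mark.parametrize("design", ALL_DESIGNS)
def test_mendelian_limit(design):
    spec = sd.DesignSpec(design, "SIMPLIFIED")
    inert = sd.build_cube(
        spec, sd.DriveParams(p=0.0, q=1.0), sd.SemParams(a=0.0, b=1.0, c=1.0), False
    )
    mendel = sd.mendelian_cube(spec)
    assert np.abs(inert.tensor - mendel.tensor).max() <= 1e-12


def test_lethal_token_mass_kept_with_zero_viability():
    cube = sd.build_cube(SIMPLE, sd.DriveParams(p=1.0, q=0.0), SP_FIG, False)
    row = cube.row("GW", "GW")
    assert row.sum() == pytest.approx(1.0)
    lethal = [o for o, lab in enumerate(cube.offspring_genotypes) if "B" in lab]
    assert sum(row[lethal]) > 0
    assert all(cube.viability[o] == 0.0 for o in lethal)


def test_induction_gating_no_sem_products_when_uninduced(rng):
    for design in ALL_DESIGNS:
        spec = sd.DesignSpec(design, "SIMPLIFIED", inducible_sem=True)
        dp, sp = random_params(rng)
        cube = sd.build_cube(spec, dp, sp, molecule_present=False)
        # crosses of pure-G parents never yield H or V offspring while uninduced
        for f, flab in enumerate(cube.female_genotypes):
            for m, mlab in enumerate(cube.male_genotypes):
                if set(flab) - {"G", "Y", "E", "w"} or set(mlab) - {"G", "Y", "E", "w"}:
                    continue
                for o, olab in enumerate(cube.offspring_genotypes):
                    if cube.tensor[f, m, o] > 0:
                        assert "H" not in olab and "V" not in olab


def test_validate_cube_flags_injected_defect(sem_release_build):
    cube = sem_release_build["cube_off"]
    assert sd.validate_cube(cube).passed
    perturbed = sd.InheritanceCube(
        spec=cube.spec,
        drive_params=cube.drive_params,
        sem_params=cube.sem_params,
        molecule_present=cube.molecule_present,
        female_genotypes=cube.female_genotypes,
        male_genotypes=cube.male_genotypes,
        offspring_genotypes=cube.offspring_genotypes,
        tensor=cube.tensor.copy(),
        viability=cube.viability,
        offspring_sex=cube.offspring_sex,
    )
    perturbed.tensor[3, 4, 0] += 0.01
    report = sd.validate_cube(perturbed)
    assert not report.passed
    assert (cube.female_genotypes[3], cube.male_genotypes[4]) in [
        (f, m) for f, m, _ in report.failing_rows
    ]


def test_mendelian_cube_validates_exactly():
    report = sd.validate_cube(sd.mendelian_cube(SIMPLE))
    assert report.passed
    assert report.max_row_deviation <= 1e-15


def test_x_linked_cube_sex_consistency():
    spec = sd.DesignSpec("CIS_X", "SIMPLIFIED")
    cube = sd.build_cube(spec, DP_FIG, SP_FIG, False)
    report = sd.validate_cube(cube)
    assert report.passed and not report.sex_violations
    for lab, sex in zip(cube.offspring_genotypes, cube.offspring_sex):
        assert ("Y" in lab) == (sex == MALE)
    # X-linked wild cross: half daughters, half sons
    row = cube.row("WW", "WY")
    assert row[cube.offspring_index["WW"]] == pytest.approx(0.5)
    assert row[cube.offspring_index["WY"]] == pytest.approx(0.5)


def test_allele_count_map(sem_release_build):
    amap = sd.allele_count_map(sem_release_build["cube_off"])
    assert amap["GW"] == {"G": 1, "W": 1}
    assert amap["HH"] == {"H": 2}
    xcube = sd.build_cube(sd.DesignSpec("CIS_X", "SIMPLIFIED"), DP_FIG, SP_FIG, False)
    assert sd.allele_count_map(xcube)["GY"] == {"G": 1}


def test_cube_round_trips_through_text_export(tmp_path, sem_release_build):
    cube = sem_release_build["cube_off"]
    sd.write_cube(cube, tmp_path / "cube")
    loaded = sd.read_cube(tmp_path / "cube")
    assert loaded.female_genotypes == cube.female_genotypes
    assert loaded.offspring_genotypes == cube.offspring_genotypes
    assert np.array_equal(loaded.tensor, cube.tensor)
    assert np.array_equal(loaded.viability, cube.viability)
    assert loaded.spec == cube.spec


def test_wild_genotype_labels():
    assert wild_genotype(SIMPLE, FEMALE).label == "WW"
    assert wild_genotype(sd.DesignSpec("CIS_X", "SIMPLIFIED"), MALE).label == "WY"
    assert wild_genotype(sd.DesignSpec("TRANS_AUTO_AUTO", "SIMPLIFIED"), MALE).label == "WWww"
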