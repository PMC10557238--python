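"""Build and inspect an inheritance cube for a self-eliminating drive.

Constructs the cis-acting autosomal design (simplified flavor, no
resistance alleles) at 50% cleavage and 100% homologous repair, and
prints the offspring distribution of a drive-heterozygote mother
crossed to a wild-type father — the heart of super-Mendelian
inheritance: 75% of offspring inherit the drive instead of 50%.
"""

import semdrive as sd

spec = sd.DesignSpec("CIS_AUTO", "SIMPLIFIED", inducible_sem=True)
drive = sd.DriveParams(p=0.5, q=1.0)  # cleavage 50%, HR 100%
sem = sd.SemParams(a=0.5, b=1.0, c=1.0)  # excision 50%, SSA repair 100%

cube = sd.build_cube(spec, drive, sem, molecule_present=False)
report = sd.validate_cube(cube)
print(f"cube: {len(cube.female_genotypes)} female x {len(cube.male_genotypes)} male "
      f"x {len(cube.offspring_genotypes)} offspring genotypes")
print(f"validation passed: {report.passed} (max row deviation {report.max_row_deviation:.1e})")

row = cube.row("GW", "WW")
print("\nGW mother x WW father ->")
for label, prob in zip(cube.offspring_genotypes, row):
    if prob > 0:
        print(f"  {label}: {prob:.4f}")
print("A Mendelian cross would give GW and WW at 0.5 each; the excess GW "
      "share is the drive's transmission bias (p*q/2 = 0.25 extra).")

# With the inducer molecule present the same cross also produces H-bearing
# offspring: the excision endonuclease is activated in drive gametes.
cube_on = sd.build_cube(spec, drive, sem, molecule_present=True)
row_on = cube_on.row("GW", "WW")
print("\nSame cross with the small molecule applied ->")
for label, prob in zip(cube_on.offspring_genotypes, row_on):
    if prob > 0:
        print(f"  {label}: {prob:.4f}")
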