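# twopeff

Benchmarking the **two-photon (2p) excitation efficiency** of ultrashort
pulsed lasers.

Two-photon microscopy depends on femtosecond pulsed lasers, and the
fluorescence a laser can excite is *not* determined by its data sheet.  For
a train of identical pulses,

    F ∝ R ∫ P(t)² dt ,

where R is the repetition rate and P(t) the single-pulse power profile.
Under an assumed pulse shape this reduces to the scalar law
F ∝ P_av² / (R·τp), with P_av the average power and τp the pulse duration
(FWHM).  Real lasers deviate from that law — energy hidden in pulse side
lobes, spurious pulses and other imperfections excite less fluorescence
than the scalars predict.  The deviation is captured by a single empiric
dimensionless factor, the 2p excitation efficiency:

    η = F_test / F_ideal = (F_test / F_ref) · (R_test · τp,test) / (R_ref · τp,ref) ,

measured against a reference laser defined to have η = 1.  A laser with
η < 1 deposits average power into the sample (heating, photodamage) that
does not come back as signal.

`twopeff` implements the full desk-scale workflow:

- **`pulses`** — parametric sech², Gaussian, square and composite
  (main-peak + side-lobe) pulse profiles on uniform time grids; energy,
  FWHM, average power.
- **`autocorr`** — intensity autocorrelation A(τ)=∫P(t)P(t+τ)dt, the
  autocorrelation time (ACF width at half maximum), and deconvolution to a
  pulse duration (factor 1.54 for sech², √2 for Gaussian, 1 for square).
- **`fluorescence`** — relative 2p fluorescence predicted from a measured
  pulse trace (e.g. a FROG trace; amplitude units are irrelevant) or from
  the scalar law; test/reference ratios.
- **`efficiency`** — log–log power-law regression of the reference laser
  (slope 2 certifies clean 2p excitation), normalized fluorescence
  F_test/F_ref, per-point η with mean ± SD, pairwise Welch tests with Holm
  adjustment, spot-size/efficiency correlations.
- **`images`** — 16-bit camera frames of the excitation volume:
  background subtraction, exposure normalization (counts/ms), brightest-
  pixel intensity, lateral and axial FWHM from the row/column profiles
  through the peak, saturation flagging.
- **`synthetic`** — generators for every input above with known ground
  truth (clean and distorted pulses tuned to a target ACF width; spot-image
  power series with Poisson shot noise, read noise and 12-bit-in-16-bit
  quantization; complete on-disk studies).
- **`io` / `cli`** — CSV/TIFF readers and writers and the `twopeff`
  command-line tool.

## Worked example

Simulate two ideal sech² pulses with identical 12.5 nJ energy (1 W average
power at 80 MHz) and compare them:

```console
$ twopeff simulate --shape sech2 --fwhm-fs 125 --energy-nj 12.5 --out trace125.csv
$ twopeff acf trace125.csv --assume sech2
ACF width: 192.85 fs
deconvolved duration (sech2): 125.23 fs
$ twopeff simulate --shape sech2 --fwhm-fs 100 --energy-nj 12.5 --out trace100.csv
$ twopeff predict-ratio trace100.csv trace125.csv --test-rate-mhz 80 --ref-rate-mhz 80
predicted fluorescence ratio (test/ref): 1.2500
```

The autocorrelation of the 125 fs pulse is 1.54× wider than the pulse
itself, and the 100 fs pulse — same energy, same repetition rate — is
predicted to excite 1.25× more fluorescence, exactly the 125/100 duration
ratio.

A complete synthetic study (six emulated lasers, six power levels from 4 to
10 mW, camera frames on disk) and its analysis:

```console
$ twopeff make-fixtures --out study --seed 7
$ twopeff spots --manifest study/manifest.csv --out spots.csv
tisa-ref: log-log slope 2.004
...
$ twopeff eta --measurements spots.csv --lasers study/lasers.csv \
      --reference tisa-ref --out-dir report
tisa-ref: F_test/F_ref = 1.000 ± 0.005, eta = 1.000 ± 0.005 (n=6)
tisa-b:   F_test/F_ref = 0.283 ± 0.005, eta = 1.000 ± 0.018 (n=6)
fiber-a:  F_test/F_ref = 0.746 ± 0.006, eta = 0.852 ± 0.007 (n=6)
fiber-b:  F_test/F_ref = 0.614 ± 0.005, eta = 0.520 ± 0.005 (n=6)
solid-a:  F_test/F_ref = 0.569 ± 0.008, eta = 1.088 ± 0.015 (n=6)
solid-b:  F_test/F_ref = 0.851 ± 0.011, eta = 0.892 ± 0.011 (n=6)
wrote report to report/report.json
```

Each line is one laser: the measured fluorescence relative to the reference
at the same power, and η after correcting for repetition rate and pulse
duration.  `tisa-b` shows why the correction matters: it produces only 28%
of the reference's fluorescence — its pulses are 3.5× longer — yet its
pulse *quality* is identical (η = 1).  The generating ground truth for this
study (`study/ground_truth.csv`) was η = 1.0, 1.0, 0.86, 0.52, 1.09, 0.90;
every value is recovered within ~2 SD.  The log–log slopes near 2 confirm
the signal is quadratic in power, i.e. genuine, unsaturated 2p excitation.

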