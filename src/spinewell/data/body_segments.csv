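# Body-segment inertial table for the trunk gravity-load distribution.
# Columns:
#   label       segment (HD = head, C1..C7 cervical, T1..T12 thoracic, L1..L5 lumbar)
#   bm_percent  segment mass as % of total body mass (head/cervical: Ivancic et al.
#               2011-era crash-dummy data; thoracolumbar: Pearsall et al. 1996).
#               The bm_percent column is authoritative for all force computations.
#   mass_kg     mass column as published alongside the percentages; shipped for
#               provenance only and NOT used (its L4/L5 entries are inconsistent
#               with bm_percent at 70.8 kg body mass, almost certainly a decimal
#               slip; 2.6% reproduces the documented 18.1 N level loads).
#   iz          sagittal mass moment of inertia about the segment's own COM axis,
#               kg*cm^2 (head/cervical rows: total values from Ivancic).
#   iz_l3       parallel-axis (Huygens-Steiner) inertia about the vertical axis
#               through the L3/L4 COM, kg*cm^2; defined for T1..L2 only.
#   d_cm        axis distance implied by iz_l3 = mass_kg * d^2, cm (T1..L2 only;
#               derived from the published columns, shipped for convenience).
#   r_mm        anteroposterior eccentricity of the segment COM anterior to the
#               vertebral center, mm.  CALIBRATED DATA: the underlying per-level
#               COM offsets are not published; a plausible profile (peaking at
#               mid-thorax, small at the cervical spine and at L3) was scaled by
#               a single factor (1.2336) so the mass-weighted mean over HD..L3
#               equals the documented 41.4 mm effective eccentricity at L3/L4.
#               L4/L5 carry their documented local eccentricities (11 mm, 4 mm).
label,bm_percent,mass_kg,iz,iz_l3,d_cm,r_mm
HD,4.7,3.300,160.0,,,18.5045
C1,0.6,0.404,0.63,,,12.3363
C2,0.7,0.508,1.10,,,12.3363
C3,0.5,0.363,0.45,,,12.3363
C4,0.5,0.366,0.47,,,12.3363
C5,0.5,0.371,0.49,,,12.3363
C6,0.6,0.439,0.69,,,12.3363
C7,0.7,0.505,1.19,,,12.3363
T1,1.1,0.811,0.498,4.49,2.3529,30.8408
T2,1.1,0.780,1.32,4.49,2.3991,37.0090
T3,1.4,0.976,3.96,4.80,2.2177,43.1771
T4,1.3,0.920,7.22,3.68,2.0000,49.3453
T5,1.3,0.945,10.6,2.66,1.6777,55.5135
T6,1.3,0.932,13.9,1.33,1.1946,61.6816
T7,1.4,0.976,18.3,0.486,0.7057,67.8498
T8,1.5,1.049,22.2,0.170,0.4026,70.3171
T9,1.6,1.096,23.9,0.011,0.1002,71.5507
T10,2.0,1.419,29.9,0.057,0.2004,67.8498
T11,2.1,1.479,28.8,0.370,0.5002,61.6816
T12,2.5,1.767,29.7,0.867,0.7004,55.5135
L1,2.4,1.677,20.8,0.612,0.6041,43.1771
L2,2.4,1.689,12.4,0.272,0.4013,30.8408
L3,2.3,1.670,5.27,,,18.5045
L4,2.6,0.180,0.218,,,11.0
L5,2.6,0.182,0.0292,,,4.0
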