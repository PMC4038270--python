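# Default synthetic-survey configuration.
#
# Cell weights follow the published ecoregion x river-type site distribution;
# severity shifts (latent-severity mean per cell) encode the qualitative
# degradation gradient: lowland (F) and Central-highland cells most degraded,
# Fenno-scandian headwaters least.  The marginals and rho below were solved by
# riverpress.synthetic.calibrate_marginals over this cell mixture so that the
# European-level group-impact prevalences are 0.41 (hydrology), 0.39
# (morphology), 0.59 (water quality) and 0.35 (segment connectivity), with 21%
# of sites unimpacted.  Edit and re-solve as needed; probabilities are
# renormalised exactly on load.
rho: 0.225367
calibration:
  group_targets: {hydrology: 0.41, morphology: 0.39, water_quality: 0.59, connectivity: 0.35}
  nop_target: 0.21

cells:
  - {ecoregion: 1, river_type: A, weight: 0.147861, shift: -0.6}
  - {ecoregion: 1, river_type: B, weight: 0.134682, shift: -0.25}
  - {ecoregion: 1, river_type: E, weight: 0.036322, shift: -0.55}
  - {ecoregion: 1, river_type: F, weight: 0.002571, shift: 0.55}
  - {ecoregion: 4, river_type: A, weight: 0.052540, shift: -0.35}
  - {ecoregion: 4, river_type: B, weight: 0.002635, shift: 0.0}
  - {ecoregion: 4, river_type: C, weight: 0.018831, shift: 0.3}
  - {ecoregion: 4, river_type: D, weight: 0.000310, shift: -0.3}
  - {ecoregion: 4, river_type: F, weight: 0.003177, shift: 0.8}
  - {ecoregion: 8, river_type: A, weight: 0.043445, shift: -0.05}
  - {ecoregion: 8, river_type: B, weight: 0.006422, shift: 0.3}
  - {ecoregion: 8, river_type: F, weight: 0.005975, shift: 1.1}
  - {ecoregion: 9, river_type: A, weight: 0.028335, shift: 0.15}
  - {ecoregion: 9, river_type: B, weight: 0.009694, shift: 0.5}
  - {ecoregion: 9, river_type: C, weight: 0.013008, shift: 0.8}
  - {ecoregion: 9, river_type: F, weight: 0.031815, shift: 1.3}
  - {ecoregion: 11, river_type: A, weight: 0.004465, shift: -0.2}
  - {ecoregion: 11, river_type: B, weight: 0.019737, shift: 0.15}
  - {ecoregion: 11, river_type: C, weight: 0.001443, shift: 0.45}
  - {ecoregion: 11, river_type: F, weight: 0.001579, shift: 0.95}
  - {ecoregion: 13, river_type: A, weight: 0.018323, shift: 0.0}
  - {ecoregion: 13, river_type: B, weight: 0.021280, shift: 0.35}
  - {ecoregion: 13, river_type: D, weight: 0.000232, shift: 0.05}
  - {ecoregion: 13, river_type: E, weight: 0.002493, shift: 0.05}
  - {ecoregion: 13, river_type: F, weight: 0.015714, shift: 1.15}
  - {ecoregion: 14, river_type: A, weight: 0.024148, shift: -0.35}
  - {ecoregion: 14, river_type: B, weight: 0.050711, shift: 0.0}
  - {ecoregion: 14, river_type: D, weight: 0.041212, shift: -0.3}
  - {ecoregion: 14, river_type: F, weight: 0.044915, shift: 0.8}
  - {ecoregion: 16, river_type: A, weight: 0.002207, shift: -0.55}
  - {ecoregion: 16, river_type: B, weight: 0.028458, shift: -0.2}
  - {ecoregion: 16, river_type: D, weight: 0.000334, shift: -0.5}
  - {ecoregion: 16, river_type: F, weight: 0.002441, shift: 0.6}
  - {ecoregion: 18, river_type: A, weight: 0.014741, shift: -0.35}
  - {ecoregion: 18, river_type: B, weight: 0.109243, shift: 0.0}
  - {ecoregion: 18, river_type: D, weight: 0.007634, shift: -0.3}
  - {ecoregion: 18, river_type: F, weight: 0.000132, shift: 0.8}
  - {ecoregion: 22, river_type: A, weight: 0.027096, shift: -1.25}
  - {ecoregion: 22, river_type: B, weight: 0.002607, shift: -0.9}
  - {ecoregion: 22, river_type: C, weight: 0.000562, shift: -0.6}
  - {ecoregion: 22, river_type: D, weight: 0.020910, shift: -1.2}

marginals:
  H_imp: {1: 0.871155, 3: 0.090192, 5: 0.038654}
  H_hydrop: {1: 0.871155, 3: 0.128845}
  H_waterabstr: {1: 0.871155, 3: 0.090192, 5: 0.038654}
  H_resflush: {1: 0.871155, 3: 0.128845}
  H_hydromod: {1: 0.871155, 3: 0.128845}
  M_channel: {1: 0.777032, 3: 0.156077, 5: 0.066890}
  M_crosssec: {1: 0.777032, 3: 0.156077, 5: 0.066890}
  M_instrhab: {1: 0.777032, 3: 0.156077, 5: 0.066890}
  M_embankm: {1: 0.660477, 2: 0.116555, 3: 0.156077, 5: 0.066890}
  M_floodpr: {1: 0.777032, 3: 0.222968}
  C_B_s_up: {1: 0.781950, 3: 0.218050}
  C_B_s_do: {1: 0.781950, 4: 0.218050}
  W_acid: {1: 0.685283, 3: 0.314717}
  W_eutroph: {1: 0.685283, 3: 0.173094, 4: 0.094415, 5: 0.047208}
  W_opoll: {1: 0.685283, 3: 0.220302, 5: 0.094415}

# [lo, median, hi] per covariate; published per-ecoregion medians and ranges.
env_ranges:
  1:
    air_temp_c: [6.9, 13.4, 18.2]
    strahler_order: [1, 3, 8]
    slope_permille: [0.01, 8.5, 774]
    altitude_m: [1, 320, 1485]
    catchment_km2: [1, 77, 96303]
    distance_from_source_km: [1, 18, 981]
  4:
    air_temp_c: [0.2, 7.6, 12.1]
    strahler_order: [1, 4, 7]
    slope_permille: [0.06, 10.5, 387]
    altitude_m: [0.01, 621, 2111]
    catchment_km2: [0.5, 92, 10017]
    distance_from_source_km: [0.1, 15, 435]
  8:
    air_temp_c: [6.1, 9.3, 13.6]
    strahler_order: [1, 2, 8]
    slope_permille: [0.036, 7.9, 165.4]
    altitude_m: [140, 441, 1340]
    catchment_km2: [0.5, 45, 51500]
    distance_from_source_km: [0.1, 11, 1380]
  9:
    air_temp_c: [5.3, 8.6, 10.4]
    strahler_order: [1, 4, 8]
    slope_permille: [0.1, 2.9, 113]
    altitude_m: [25, 301, 856]
    catchment_km2: [1, 351, 147809]
    distance_from_source_km: [0.1, 41, 984]
  11:
    air_temp_c: [8.0, 10.0, 11.3]
    strahler_order: [1, 3.5, 8]
    slope_permille: [0.1, 1.3, 32.7]
    altitude_m: [79, 128, 387]
    catchment_km2: [0.5, 100, 100161]
    distance_from_source_km: [0.1, 39, 1454]
  13:
    air_temp_c: [8.3, 10.7, 15.6]
    strahler_order: [1, 3, 8]
    slope_permille: [0.01, 2.0, 63]
    altitude_m: [0, 84, 865]
    catchment_km2: [2, 214, 185000]
    distance_from_source_km: [1, 29, 1078]
  14:
    air_temp_c: [4.4, 8.0, 10.2]
    strahler_order: [1, 3, 8]
    slope_permille: [0.01, 1.0, 76.6]
    altitude_m: [0, 44, 370]
    catchment_km2: [2, 209.5, 10469.3]
    distance_from_source_km: [0.1, 27, 1080]
  16:
    air_temp_c: [6.4, 7.6, 10.2]
    strahler_order: [1, 3, 8]
    slope_permille: [0.01, 1.0, 27.9]
    altitude_m: [0, 107, 452]
    catchment_km2: [4, 513, 195208]
    distance_from_source_km: [2, 53.5, 988]
  18:
    air_temp_c: [6.8, 9.6, 10.8]
    strahler_order: [1, 2, 6]
    slope_permille: [0.01, 3.1, 242.9]
    altitude_m: [0, 49, 353]
    catchment_km2: [1, 70, 9653]
    distance_from_source_km: [1, 16, 252]
  22:
    air_temp_c: [-2.3, 1.3, 5.2]
    strahler_order: [1, 3, 6]
    slope_permille: [0.1, 2.7, 79.3]
    altitude_m: [1, 129, 480]
    catchment_km2: [2, 693, 40157]
    distance_from_source_km: [2, 68, 530]

# log(inhabitants/km2) = mu0 + beta * latent severity + sigma * noise
pop_density: {mu0: 3.912, beta: 0.6, sigma: 1.0}
p_disconnected: 0.85
countries: {1: ES, 4: AT, 8: CH, 9: AT, 11: HU, 13: FR, 14: DE, 16: PL, 18: UK, 22: FI}
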