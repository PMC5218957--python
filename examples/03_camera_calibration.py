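"""Determine the camera normalization factor (CNF) three ways.

Planar method 1 uses all photopeak counts of a point-source scan and is
biased up by scatter; planar method 2 first removes the TEW scatter
estimate; the tomographic method reconstructs a phantom scan and divides
total image counts by activity x total scan time.  All three should agree
(method 1 excepted) with the simulated detector sensitivity of
10 counts/(MBq s).
"""

from luquant import AcquisitionSpec, VoxelGrid, build_phantom, cnf_tomo_config
from luquant import calibration as cal
from luquant.analysis import scatter_params_for
from luquant.recon import osem, tew_estimate
from luquant.simulate import (recon_projector, simulate_acquisition,
                              simulate_planar_point_source)

# planar point source: 11.7 MBq, 10 min, 30 cm from the collimator
planar = simulate_planar_point_source(11.7, 600.0, sensitivity=10.0, seed=3)
rec = cal.PlanarScanRecord(C_pw=float(planar["pw"].sum()),
                           C_ls=float(planar["lsw"].sum()),
                           C_us=float(planar["usw"].sum()), A=11.7, t_d=600.0)
m1 = cal.cnf_planar_method1(rec)
m2 = cal.cnf_planar_method2(rec)
print(f"planar method 1 (no scatter correction): {m1.value:.3f} counts/(MBq s)")
print(f"planar method 2 (TEW corrected):         {m2.value:.3f} counts/(MBq s)")

# tomographic: bottle phantom at 233.4 MBq total, reconstructed with TEW
cfg = cnf_tomo_config(233.4, in_air=True)
phantom = build_phantom(cfg, VoxelGrid((128, 128, 128), 2.4))
acq = AcquisitionSpec(n_projections=90, detector_shape=(64, 64), bin_size=4.8,
                      t_p=cfg.projection_duration, sensitivity=10.0)
sim = simulate_acquisition(phantom, acq, scatter_params_for(cfg))
noisy = sim.realize(seed=4)
img = osem(noisy["pw"], recon_projector(phantom, acq), tew_estimate(noisy))
tomo = cal.cnf_tomographic(cal.TomoScanRecord(
    C_rec=img.total_counts, A=phantom.total_activity_MBq,
    n_p=acq.n_projections, t_p=acq.t_p))
print(f"tomographic (TEW-corrected OSEM):        {tomo.value:.3f} counts/(MBq s)")
# method 2 and the tomographic value bracket the true sensitivity (10);
# method 1 sits ~8% high - the self-scatter plus high-energy downscatter
# fraction present in the photopeak window.
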