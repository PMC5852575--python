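"""Hydrogen-bond detection and time averaging on exact geometries.

A donor(N)–H···acceptor(O) fixture is built at requested distance/angle,
checked against the default geometric criteria (3.5 Å, 30°), and a
100-frame ensemble toggling the bond on a known schedule shows the time
average equals the schedule fraction exactly.
"""

import numpy as np

import rnaocclusion as ro

protein = ro.Selection(chains={"A"})
rna = ro.Selection(chains={"R"})

for distance, angle in ((2.9, 10.0), (3.6, 10.0), (2.9, 35.0)):
    fixture = ro.make_hbond_fixture(distance, angle)
    bonds = ro.detect_hbonds(fixture, protein, rna)
    verdict = "bond" if bonds else "no bond"
    print(f"d(N,O) = {distance} Å, H-N-O angle = {angle}° → {verdict}")

bonded = ro.make_hbond_fixture(2.9, 10.0)
broken = ro.make_hbond_fixture(5.0, 10.0)
frames = np.array([bonded.coords if f < 40 else broken.coords
                   for f in range(100)])
series = ro.hbond_time_average(ro.Ensemble(bonded.copy(), frames),
                               [("A", 1)], rna)
print(f"\nbond present in 40 of 100 frames → time average "
      f"{series.residue_means[('A', '1')]:.2f} bonds/frame")
print("The time average is the per-frame bond count between the residue")
print("and the RNA, averaged over the whole ensemble.")
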