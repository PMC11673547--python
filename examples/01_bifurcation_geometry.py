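"""Build Murray's-law bifurcation geometries and report their angles.

The three adjustable parameters are the bifurcation index n, the radius
ratio r = rd1^n/rd2^n and the total bifurcation angle A.  For n = 3 the
energy-optimal angle is close to 75 degrees; asymmetric daughters (r < 1)
shift it slightly.
"""

from arterysph import build_bifurcation
from arterysph.studies import murray_angle

for r in (0.4, 0.7, 1.0):
    print(f"r = {r}: optimal total angle A = {murray_angle(r):.2f} deg")

spec = build_bifurcation(n=3, r=0.7, rp=0.06)
print(
    f"\nn=3, r=0.7, rp=60 mm -> daughters {1e3 * spec.rd1:.1f} / {1e3 * spec.rd2:.1f} mm, "
    f"alpha={spec.alpha:.2f} deg, beta={spec.beta:.2f} deg"
)
print("Murray identity rd1^3 + rd2^3 =", spec.rd1**3 + spec.rd2**3, "~ rp^3 =", spec.rp**3)
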