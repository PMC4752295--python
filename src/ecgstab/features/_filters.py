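"""Frozen orthonormal filter tables used by the wavelet machinery.

All filters are decomposition *lowpass* taps of orthonormal two-channel
banks (unit l2 norm, sum sqrt(2), double-shift orthogonal). Highpass
partners are derived by quadrature mirroring, see :mod:`ecgstab.wavelets`.

``QSHIFT_14`` is an even-length filter whose group delay sits a quarter
sample off centre; pairing it with its time reverse in the second tree of
a dual-tree transform yields the half-sample delay difference that makes
the complex wavelets approximately analytic. The taps were refined to
satisfy the orthonormality constraints to < 1e-16.
"""

import numpy as np

# Daubechies 4 (8 taps) - used for the level-10 low-frequency removal filter.
DB4 = np.array([
    -1.05974017850690317e-02, 3.28830116668851966e-02,
    3.08413818355607640e-02, -1.87034811719093086e-01,
    -2.79837694168598543e-02, 6.30880767929858921e-01,
    7.14846570552915672e-01, 2.30377813308896506e-01,
])

# Daubechies 10 (20 taps) - first level of the dual-tree transform.
DB10 = np.array([
    -1.32642028945212443e-05, 9.35886703200695919e-05,
    -1.16466855129285449e-04, -6.85856694959711619e-04,
    1.99240529518505613e-03, 1.39535174705290106e-03,
    -1.07331754833305745e-02, 3.60655356695616970e-03,
    3.32126740593410019e-02, -2.94575368218758134e-02,
    -7.13941471663970817e-02, 9.30573646035723484e-02,
    1.27369340335793252e-01, -1.95946274377377050e-01,
    -2.49846424327315381e-01, 2.81172343660577473e-01,
    6.88459039453603538e-01, 5.27201188931725628e-01,
    1.88176800077691497e-01, 2.66700579005555542e-02,
])

# 14-tap Q-shift lowpass (tree A, levels >= 2 of the dual tree).
QSHIFT_14 = np.array([
    3.25313043190723385e-03, -3.88319866850503565e-03,
    3.46602411742924360e-02, -3.88726931997839739e-02,
    -1.17204013956674929e-01, 2.75295479136275889e-01,
    7.56145532661265496e-01, 5.68810534681604474e-01,
    1.18659794213559454e-02, -1.06711694003204530e-01,
    2.38253794774058412e-02, 1.70252179975179697e-02,
    -5.43945571966283296e-03, -4.55687706069887646e-03,
])
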