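# Synthetic contact-interaction potential (210 parameters).
# NOT an empirically derived knowledge-based potential: constructed as
# U = eps*h*h^T + small symmetric noise (eps = -4.0, noise sd 0.01, seed
# 20260927), where h is a Kyte-Doolittle-derived hydrophobicity scale
# rescaled to unit L2 norm and mean 0.14 over the 20 amino acids.
# Units: kT at the reference temperature. Lower triangle incl. diagonal,
# row i has i+1 entries. Amino-acid ordering (PAML):
# A R N D C Q E G H I L K M F P S T W Y V
-0.327779
 0.101385 -0.032858
 0.037947  0.001100  0.014978
 0.044483 -0.023947 -0.006958 -0.010674
-0.352725  0.124886  0.040197  0.041521 -0.404778
 0.049273 -0.011103 -0.006309 -0.009139  0.047738 -0.013357
 0.024153 -0.016395 -0.004553 -0.003957  0.046757  0.003706 -0.006159
-0.150601  0.055126  0.031139  0.019816 -0.197046  0.020519  0.030349 -0.094189
 0.034125 -0.015751 -0.001854 -0.004557  0.029876 -0.007389 -0.008824  0.022551  0.001015
-0.480436  0.171000  0.072371  0.054764 -0.562369  0.068562  0.065854 -0.255213  0.043598 -0.765294
-0.447920  0.155675  0.064726  0.074032 -0.504624  0.059044  0.078441 -0.227829  0.026057 -0.703236 -0.640257
 0.072580 -0.026987  0.000998 -0.014798  0.088941 -0.011577 -0.009325  0.041425 -0.016937  0.109113  0.104143 -0.027537
-0.300887  0.113871  0.048606  0.053515 -0.373573  0.057813  0.036150 -0.165086  0.018482 -0.490215 -0.443391  0.071523 -0.319879
-0.377176  0.142961  0.050812  0.045872 -0.435448  0.059238  0.064950 -0.201496  0.023648 -0.594946 -0.538100  0.090000 -0.376687 -0.462932
-0.081127  0.015553  0.012145  0.011756 -0.084641 -0.003222  0.011951 -0.051429 -0.004948 -0.128223 -0.118237  0.012556 -0.087210 -0.097644 -0.014952
-0.125429  0.061840  0.022137  0.010035 -0.152236  0.015682  0.022485 -0.075797  0.001476 -0.206774 -0.193924  0.023071 -0.141101 -0.161526 -0.034914 -0.060469
-0.151655  0.049388  0.021204  0.025191 -0.163401  0.028168  0.016551 -0.080826  0.009171 -0.232068 -0.199246  0.024184 -0.143276 -0.172088 -0.036585 -0.044992 -0.054011
-0.126225  0.044581  0.029012  0.014754 -0.139152  0.025076  0.029870 -0.065311  0.009293 -0.194521 -0.181132  0.037827 -0.124938 -0.151702 -0.046705 -0.041699 -0.051450 -0.076857
-0.107439  0.021361  0.013700  0.013011 -0.120380  0.011200  0.011784 -0.059423  0.011760 -0.171216 -0.146156  0.022546 -0.104223 -0.135662 -0.031634 -0.035603 -0.045401 -0.040641 -0.026907
-0.446186  0.173822  0.073427  0.080098 -0.539809  0.074145  0.072921 -0.241451  0.038655 -0.740567 -0.657772  0.109531 -0.481852 -0.580090 -0.121229 -0.200272 -0.204680 -0.190965 -0.152524 -0.700005
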