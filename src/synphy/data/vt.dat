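  0.233108
  0.199097   0.210797
  0.265145   0.105191   0.883422
  0.227333   0.031726   0.027495   0.010313
  0.310084   0.493763     0.2757   0.205842   0.004315
  0.567957    0.25524   0.270417   1.599461   0.005321   0.960976
  0.876213   0.156945   0.362028   0.311718   0.050876    0.12866   0.250447
  0.078692   0.213164   0.290006   0.134252   0.016695   0.315521   0.104458   0.058131
  0.222972    0.08151   0.087225    0.01172   0.046398   0.054602   0.046589   0.051089   0.020039
   0.42463   0.192364   0.069245   0.060863   0.091709    0.24353   0.151924   0.087056   0.103552    2.08989
  0.393245   1.755838    0.50306   0.261101   0.004067   0.738208    0.88863   0.193243   0.153323   0.093181   0.201204
   0.21155    0.08793    0.05742   0.012182    0.02369   0.120801   0.058643    0.04656   0.021157   0.493845   1.105667   0.096474
  0.116646   0.042569   0.039769   0.016577   0.051127   0.026235   0.028168   0.050143   0.079807    0.32102   0.946499   0.038261   0.173052
  0.399143    0.12848   0.083956   0.160063   0.011137    0.15657   0.205134   0.124492   0.078892   0.054797   0.169784   0.212302   0.010363   0.042564
  1.817198   0.292327   0.847049   0.461519    0.17527   0.358017   0.406035   0.612843   0.167406   0.081567   0.214977   0.400072   0.090515   0.138119   0.430431
  0.877877   0.204109   0.471268   0.178197   0.079511   0.248992   0.321028   0.136266   0.101117   0.376588   0.243227   0.446646   0.184609    0.08587   0.207143   1.767766
  0.030309   0.046417   0.010459   0.011393   0.007732   0.021248   0.018844    0.02399   0.020009   0.034954   0.083439   0.023321   0.022019    0.12805   0.014584   0.035933   0.020437
  0.087061    0.09701   0.093268   0.051664   0.042823   0.062544     0.0552   0.037568   0.286027   0.086237   0.189842   0.068689   0.073223   0.898663   0.032043   0.121979   0.094617   0.124746
  1.230985   0.113146   0.049824   0.048769   0.163831   0.112027   0.205868   0.082579   0.068575    3.65443   1.337571   0.144587   0.307309   0.247329   0.129315     0.1277   0.740372   0.022134   0.125733

0.0788369212 0.0512379488 0.0423129577 0.0530659469 0.0151749848 0.0367129633 0.0619239381 0.0708519291 0.0230819769 0.0620559379 0.0963709036 0.0573239427 0.0237709762 0.0432959567 0.0439109561 0.0634029366 0.0558969441 0.0132719867 0.0343989656 0.0731009269
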