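0.73579039
0.485391055 1.29744671
0.543161821 0.500964409 3.18010005
1.45999531 0.227826574 0.39735895 0.240836615
 1.1997057 3.02083361 1.83921615  1.1909457 0.329801505
1.17094904 1.36057419 1.24048851 3.76162521 0.140748892 5.52891918
1.95588357 0.418763309 1.35587234 0.798473249 0.418203192 0.609846305 0.423579992
0.716241445 1.45614117 2.41450143 0.778142664 0.35405811 2.43534113 1.62689106 0.539859125
0.605899004 0.232036445 0.283017326 0.418555732 0.774894023 0.236202451 0.186848047 0.189296292 0.252718448
0.800016531 0.62271167 0.21188816 0.218131578 0.83184264 0.580737093 0.372625175 0.217721159 0.34807221 3.89096377
1.29520127 5.41111514 1.59313704 1.03244792 0.285078801 3.94527767 2.80242715 0.75204244 1.02250704 0.406193587 0.445570274
1.25375827 0.983692987 0.648441279 0.222621898 0.767688823 2.49489608 0.555415397 0.459436174 0.984311525 3.36479776 6.03055938 1.07306118
0.49296468 0.371644693 0.354861249 0.281730694 0.441337471 0.14435696 0.291409084 0.368166464 0.714533704 1.51735933  2.0648397 0.266924751 1.77385517
 1.1732759 0.448133662 0.494887044 0.730628273 0.356008499 0.858570576 0.926563935  0.5040866 0.527007339 0.388355409 0.374555687 1.04738345 0.454123625 0.23359791
4.32509269  1.1227831 2.90410166 1.58275414 1.19718842 1.93487092 1.76989324 1.50932625 1.11702976 0.357544412 0.352969185 1.75216592 0.918723416 0.540027645 1.16912958
1.72917802 0.914665955 1.89817363 0.934187509 1.11983136 1.27748029 1.07109724 0.641436011 0.58540709  1.1790912 0.915259858  1.3038752 1.48854805 0.488206119 1.00545168 5.15155629
0.465839368 0.42638231 0.191482046 0.145345046 0.527664419 0.758653809 0.407635649 0.508358925 0.301248601 0.341985788 0.691474635 0.332243041 0.888101098 2.07432489 0.25221483 0.387925622 0.513128127
0.718206698 0.720517441 0.538222519 0.261422209 0.470237734 0.958989743  0.5967193 0.308055737 4.21895397 0.674617093 0.811245856 0.717993487 0.951682162 6.74726043 0.369405319 0.796751521 0.801010243 4.05441901
2.18777452 0.438388344 0.312858798 0.258129289 1.11635248 0.53078579 0.524253846 0.25334079 0.201555972 8.31183941 2.23140569 0.498138475 2.57585076 0.83811961 0.496908411 0.561925457 2.25307405 0.266508731          1

     0.074      0.052      0.045      0.054      0.025      0.034      0.054      0.074      0.026      0.068      0.099      0.058      0.025      0.047      0.039      0.057      0.051      0.013      0.032      0.073
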