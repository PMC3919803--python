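        27
        98         32
       120          0        905
        36         23          0          0
        89        246        103        134          0
       198          1        148       1153          0        716
       240          9        139        125         11         28         81
        23        240        535         86         28        606         43         10
        65         64         77         24         44         18         61          0          7
        41         15         34          0          0         73         11          7         44        257
        26        464        318         71          0        153         83         27         26         46         18
        72         90          1          0          0        114         30         17          0        336        527        243
        18         14         14          0          0          0          0         15         48        196        157          0         92
       250        103         42         13         19        153         51         34         94         12         32         33         17         11
       409        154        495         95        161         56         79        234         35         24         17         96         62         46        245
       371         26        229         66         16         53         34         30         22        192         33        136        104         13         78        550
         0        201         23          0          0          0          0          0         27          0         46          0          0         76          0         75          0
        24          8         95          0         96          0         22          0        127         37         28         13          0        698          0         34         42         61
       208         24         15         18         49         35         37         54         44        889        175         10        258         12         48         30        157          0         28

0.0871269129 0.0409039591 0.0404319596 0.0468719531 0.0334739665 0.0382549617 0.0495299505 0.0886119114 0.0336179664 0.0368859631 0.0853569146 0.0804819195 0.0147529852 0.0397719602 0.0506799493 0.0695769304 0.0585419415 0.0104939895 0.0299159701 0.0647179353
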