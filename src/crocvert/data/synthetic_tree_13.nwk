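(((((sp01:2.0,sp02:2.0):2.0,sp03:4.0):2.0,sp04:6.0):74.0,((sp05:2.0,sp06:2.0):2.0,sp07:4.0):76.0):7.14,(((sp08:2.0,sp09:2.0):2.0,sp10:4.0):76.0,((sp11:2.0,sp12:2.0):2.0,sp13:4.0):76.0):7.14);
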