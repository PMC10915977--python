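A	B	C	D	E
0.1787625811430533	0.35193883162538625	0.3678745626677189	-0.05909465455975235	0.4602769187712337
0.35193883162538625	0.1787625811430533	0.3678745626677189	-0.05909465455975235	0.4602769187712337
-0.06144963726792461	0.39104314625042913	0.22846946523574121	-0.12099338995127076	-0.01054173113790689
0.039104314625042914	0.2625575410538596	0.20910764614796656	0.2164561859508377	0.2553379866095247
0.13965826651801042	0.13965826651801042	0.19361819087774682	0.4478997141602233	0.3856871084032742
0.2625575410538596	0.039104314625042914	0.20910764614796656	0.2164561859508377	0.2553379866095247
0.39104314625042913	-0.06144963726792461	0.22846946523574121	-0.12099338995127076	-0.01054173113790689
-0.27931653303602083	0.27931653303602083	0.0	-0.1868329970615376	-0.16413422117214227
-0.13965826651801042	0.13965826651801042	0.0	0.20183794392782173	-0.09082462884644864
1.1540862686988258e-18	-2.3081725373976515e-18	0.0	0.5263956674854845	-0.029607820768124033
0.13965826651801042	-0.13965826651801042	0.0	0.20183794392782173	-0.09082462884644864
0.27931653303602083	-0.27931653303602083	0.0	-0.1868329970615376	-0.16413422117214227
-0.39104314625042913	0.06144963726792461	-0.22846946523574121	-0.22941692596609745	-0.18269376539827753
-0.2625575410538596	-0.039104314625042914	-0.20910764614796656	-0.08144021959273162	-0.17616519809211775
-0.13965826651801042	-0.13965826651801042	-0.19361819087774682	0.036897806778027425	-0.1695914892383646
-0.039104314625042914	-0.2625575410538596	-0.20910764614796656	-0.08144021959273162	-0.17616519809211775
0.06144963726792461	-0.39104314625042913	-0.22846946523574121	-0.22941692596609745	-0.18269376539827753
-0.35193883162538625	-0.1787625811430533	-0.3678745626677189	-0.24611253695913768	-0.1844992599322588
-0.1787625811430533	-0.35193883162538625	-0.3678745626677189	-0.24611253695913768	-0.1844992599322588
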