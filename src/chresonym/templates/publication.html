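{% extends "base.html" %}
{% block title %}{{ entry.publication.key }}{% endblock %}
{% block heading %}{{ entry.publication.key }} ({{ entry.publication.year }}){% endblock %}
{% block content %}
{% if entry.publication.citation_text %}
<p class="citation">{{ entry.publication.citation_text }}</p>
{% endif %}
<h2>Names used</h2>
<table>
<tr><th>Name</th><th>Where</th><th>Context</th><th>Accepted species</th></tr>
{% for row in entry.rows %}
<tr>
  <td><a href="{{ links.binomial(row.name) }}"><em>{{ row.name }}</em></a></td>
  <td>{{ row.locus }}</td>
  <td>{{ row.context_summary }}</td>
  <td>{{ row.accepted_display }}</td>
</tr>
{% endfor %}
</table>
<h2>Cited by</h2>
{% if entry.cited_by %}
<ul>
{% for key in entry.cited_by %}
  <li><a href="{{ links.publication(key) }}">{{ key }}</a></li>
{% endfor %}
</ul>
{% else %}
<p>No name-record citations.</p>
{% endif %}
{% endblock %}
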